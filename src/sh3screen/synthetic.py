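"""Seeded generators emulating the panning and array experiments.

Biopanning is modeled as single-hit capture: the chance that a phage
displaying SH3 domain *i* is retained on the bait is proportional to its
library abundance times its capture weight, with a small floor for
nonspecific retention (empty-bead controls retain a trickle of unbiased
phages).  Each round feeds the post-capture frequencies back as the next
round's abundances; sequencing draws a multinomial sample of clones from
the final frequencies.  Amplification bias between rounds is not modeled.

Array slides are generated as baseline + truth x lognormal multiplicative
noise; lognormal rather than additive Gaussian because spot signals are
non-negative and probe concentrations span an order of magnitude.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_quant import ArraySlide
from .motif_scan import AMINO_ACIDS, ProteinTail
from .phage_selection import (
    EnrichmentFactor,
    ScreenResult,
    SelectionProfile,
    SH3Library,
    TierThresholds,
    classify_selection,
    design_reduction_library,
)


@dataclass(frozen=True)
class AffinityProfile:
    """Relative capture weights of one ADAM tail for each SH3 domain.

    Weight 1.0 is background level (nonspecific retention); unlisted SH3s
    default to it.  Weights are relative, not probabilities.
    """

    adam_id: str
    weight: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weight.values()):
            raise ValueError("negative capture weight")

    def weight_for(self, sh3: str) -> float:
        return float(self.weight.get(sh3, 1.0))


@dataclass(frozen=True)
class PanningConfig:
    """Panning simulation parameters.

    Two rounds of capture by default (one round rarely drives a strong
    binder past the dominance threshold); 150 sequenced clones per screen,
    matching the scale of real per-screen sequencing depth.
    """

    rounds: int = 2
    clones_sequenced: int = 150
    seed: int = 0
    background_capture: float = 0.01

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.clones_sequenced < 1:
            raise ValueError("clones_sequenced must be >= 1")
        if self.background_capture <= 0:
            raise ValueError("background_capture must be > 0")


def capture_frequencies(library: SH3Library, profile: AffinityProfile,
                        config: PanningConfig) -> tuple[list[str], np.ndarray]:
    """Post-capture frequencies after ``config.rounds`` rounds (no sampling).

    One round maps abundances a to a_i w~_i / sum_j a_j w~_j with
    w~ = max(weight, background floor); excluded SH3s stay at zero.
    """
    members = library.members
    if not members:
        raise ValueError("library has no members")
    a = np.array([library.abundance[m] for m in members], dtype=float)
    w = np.array([max(profile.weight_for(m), config.background_capture)
                  for m in members], dtype=float)
    if not (a * w).sum() > 0:
        raise ValueError("all effective capture weights are zero")
    for _ in range(config.rounds):
        a = a * w
        a /= a.sum()
    return members, a


def simulate_panning(library: SH3Library, profile: AffinityProfile,
                     config: PanningConfig, screen_id: str | None = None,
                     full_library: bool = True) -> ScreenResult:
    """One complete panning experiment ending in clone sequencing.

    Counts are a multinomial draw of ``clones_sequenced`` from the final
    post-capture frequencies, deterministic given the seed.  The simulated
    enrichment factor is the mean capture weight over the background floor.
    """
    members, freq = capture_frequencies(library, profile, config)
    rng = np.random.default_rng(config.seed)
    draws = rng.multinomial(config.clones_sequenced, freq)
    counts = {m: int(c) for m, c in zip(members, draws) if c > 0}
    a = np.array([library.abundance[m] for m in members])
    w = np.array([profile.weight_for(m) for m in members])
    enrichment = EnrichmentFactor(float((a * w).sum() / (a.sum() * config.background_capture)))
    if screen_id is None:
        screen_id = f"{profile.adam_id}:{library.library_id}:seed{config.seed}"
    return ScreenResult(screen_id, profile.adam_id, library.library_id, counts,
                        enrichment=enrichment, full_library=full_library)


def simulate_screen_series(library: SH3Library, profile: AffinityProfile,
                           config: PanningConfig,
                           thresholds: TierThresholds = TierThresholds(),
                           reduction_policy: Sequence[str] = ("dominant",),
                           screens_per_library: int = 2,
                           max_stages: int | None = None) -> list[ScreenResult]:
    """Sequential screening: pan, exclude dominant binders, pan again.

    Each library stage is screened ``screens_per_library`` times with
    distinct seeds (emulating independently prepared libraries).  SH3s
    that dominate the clones of the current stage are excluded from the
    next stage's reduction library; the series stops when no SH3 dominates
    or exclusion would empty the library.
    """
    if max_stages is None:
        max_stages = len(library.members)  # termination bound: finite set
    screens: list[ScreenResult] = []
    lib = library
    for stage in range(max_stages):
        full = stage == 0
        stage_screens = []
        for i in range(screens_per_library):
            cfg = replace(config, seed=config.seed + 1000 * stage + i)
            scr = simulate_panning(
                lib, profile, cfg,
                screen_id=f"{profile.adam_id}:s{stage}r{i}", full_library=full)
            stage_screens.append(scr)
        screens.extend(stage_screens)
        # dominance within the current stage decides the next exclusions
        stage_view = [replace(s, full_library=True) for s in stage_screens]
        stage_profile = classify_selection(stage_view, thresholds)
        if not any(stage_profile.in_tier(t) for t in reduction_policy):
            break
        try:
            lib = design_reduction_library(lib, stage_profile, drop_tiers=reduction_policy)
        except ValueError:
            break  # library floor reached
    return screens


def simulate_array(truth: pd.DataFrame, noise_cv: float = 0.1,
                   background_mean: float = 100.0, background_sd: float = 10.0,
                   seed: int = 0, n_empty: int = 33) -> list[ArraySlide]:
    """Array slides (one per probe column of ``truth``) with known binding.

    Raw spot signal = baseline ~ Normal(background_mean, background_sd)
    truncated at 0, plus truth x lognormal noise with unit mean and the
    given coefficient of variation; three replicates per peptide and
    ``n_empty`` empty spots per slide.
    """
    if (truth.values < 0).any():
        raise ValueError("truth values must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(noise_cv ** 2)
    mu, sigma = -sigma2 / 2, math.sqrt(sigma2)
    slides = []
    for probe in truth.columns:
        empties = np.clip(rng.normal(background_mean, background_sd, n_empty), 0, None)
        spots = {}
        for pep in truth.index:
            base = np.clip(rng.normal(background_mean, background_sd, 3), 0, None)
            noise = rng.lognormal(mu, sigma, 3) if sigma > 0 else np.ones(3)
            spots[pep] = list(base + float(truth.loc[pep, probe]) * noise)
        slides.append(ArraySlide(f"slide-{probe}", str(probe), spots, list(empties)))
    return slides


def plant_motif_tail(length: int, planted_specs: Sequence[tuple[str, int]],
                     seed: int = 0,
                     background_alphabet: str | None = None) -> ProteinTail:
    """A random tail with known motif instances at recorded positions.

    ``planted_specs`` is a list of (motif instance, 1-based start).  The
    background is drawn uniformly from ``background_alphabet`` — by
    default the 20 residues minus proline, so the background cannot form
    PxxP-core motifs by chance.  Overlapping planted motifs raise
    ``ValueError``.
    """
    if background_alphabet is None:
        background_alphabet = "".join(sorted(AMINO_ACIDS - {"P"}))
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(background_alphabet), size=length))
    occupied = [False] * length
    for motif, start in planted_specs:
        end = start + len(motif) - 1
        if start < 1 or end > length:
            raise ValueError(f"planted motif {motif!r} at {start} exceeds tail length {length}")
        span = range(start - 1, end)
        if any(occupied[i] for i in span):
            raise ValueError(f"planted motif {motif!r} at {start} overlaps another plant")
        for i, c in zip(span, motif):
            occupied[i] = True
            seq[i] = c
    return ProteinTail(id=f"synthetic-{seed}", sequence="".join(seq),
                       source=f"synthetic tail, seed={seed}, planted={list(planted_specs)!r}")


def profile_from_tiers(adam_id: str, tiers: Mapping[str, str],
                       dominant_weight: float = 50.0, strong_weight: float = 10.0,
                       enriched_weight: float = 3.0) -> AffinityProfile:
    """Capture-weight profile emulating a tiered selection outcome."""
    level = {"dominant": dominant_weight, "strongly_selected": strong_weight,
             "significantly_enriched": enriched_weight}
    weights = {sh3: level[t] for sh3, t in tiers.items() if t in level}
    return AffinityProfile(adam_id, weights)
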