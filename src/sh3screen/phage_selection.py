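"""Phage-display selection statistics and tiered partner classification.

A biopanning screen against one ADAM tail yields clone counts per SH3
domain.  Apparent binders are classified into three tiers — *dominant*,
*strongly selected* and *significantly enriched* — from the clone-count
evidence across repeated screens, and dominant binders are removed from
the library to build "reduction libraries" that reveal weaker partners in
subsequent rounds of panning.

The tiers are qualitative in origin; the numeric thresholds used here
(:class:`TierThresholds`) are package defaults, echoed in every report,
and fully configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import pandas as pd

TIERS = ("dominant", "strongly_selected", "significantly_enriched", "none")


@dataclass(frozen=True)
class EnrichmentFactor:
    """Retained-phage ratio vs background, e.g. ``3000`` or ``>10,000``.

    ``lower_bound`` marks values reported as ">N": the measurement
    saturated and the true factor is at least ``value``.
    """

    value: float
    lower_bound: bool = False

    @classmethod
    def parse(cls, text: str | float | int) -> "EnrichmentFactor":
        if not isinstance(text, str):
            return cls(float(text))
        raw = text.strip()
        lower = raw.startswith(">")
        num = raw.lstrip(">").replace(",", "").strip()
        if not re.fullmatch(r"\d+(\.\d+)?", num):
            raise ValueError(f"unparseable enrichment factor {text!r}")
        return cls(float(num), lower_bound=lower)

    def __str__(self) -> str:
        v = int(self.value) if self.value == int(self.value) else self.value
        return f">{v:,}" if self.lower_bound else f"{v:,}"


@dataclass
class SH3Library:
    """An SH3 phage library: relative abundances plus an exclusion set."""

    library_id: str
    abundance: dict[str, float]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.excluded = frozenset(self.excluded)
        if any(a < 0 for a in self.abundance.values()):
            raise ValueError("negative abundance")
        for sh3 in self.excluded:
            self.abundance[sh3] = 0.0
        total = sum(self.abundance.values())
        if total <= 0:
            raise ValueError(f"library {self.library_id!r} has no positive abundance")
        self.abundance = {k: v / total for k, v in self.abundance.items()}

    @property
    def members(self) -> list[str]:
        """SH3 ids with positive abundance, sorted."""
        return sorted(k for k, v in self.abundance.items() if v > 0)

    @classmethod
    def uniform(cls, domains: Sequence[str], library_id: str = "full",
                excluded: Sequence[str] = ()) -> "SH3Library":
        ab = {d: 1.0 for d in domains}
        for d in excluded:
            ab[d] = 0.0
        return cls(library_id, ab, frozenset(excluded))

    @classmethod
    def from_yaml(cls, source: IO[str] | str) -> "SH3Library":
        import yaml

        if isinstance(source, str):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        if isinstance(doc.get("domains"), Mapping):
            ab = {k: float(v) for k, v in doc["domains"].items()}
        else:
            ab = {d: 1.0 for d in doc["domains"]}
        excluded = frozenset(doc.get("excluded", ()))
        for d in excluded:
            ab.setdefault(d, 0.0)
        return cls(doc.get("library_id", "library"), ab, excluded)


def default_library() -> SH3Library:
    """The shipped default library (lacks Crk(II) and CrkL(II))."""
    from importlib.resources import files

    return SH3Library.from_yaml(str(files("sh3screen.data") / "sh3_library.yaml"))


@dataclass
class ScreenResult:
    """Clone counts per SH3 domain from one panning experiment."""

    screen_id: str
    adam_id: str
    library_id: str
    counts: dict[str, int]
    enrichment: EnrichmentFactor | None = None
    full_library: bool = True

    def __post_init__(self) -> None:
        for sh3, c in self.counts.items():
            if c < 0:
                raise ValueError(f"{self.screen_id}: negative clone count for {sh3}")

    @property
    def total_clones(self) -> int:
        return sum(self.counts.values())


@dataclass
class SelectionProfile:
    """Tier per SH3 domain for one ADAM, with supporting evidence."""

    adam_id: str
    tier: dict[str, str]
    evidence: dict[str, dict]
    thresholds: "TierThresholds"

    def in_tier(self, tier: str) -> list[str]:
        return sorted(s for s, t in self.tier.items() if t == tier)

    @property
    def selected(self) -> list[str]:
        """All SH3 ids in any of the three selection tiers."""
        return sorted(s for s, t in self.tier.items() if t != "none")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"adam_id": self.adam_id, "sh3_id": s, "tier": t, **self.evidence[s]}
            for s, t in sorted(self.tier.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TierThresholds:
    """Numeric tier criteria (package defaults; echoed in reports).

    dominant          — clone fraction >= ``dominant_fraction`` in at least
                        one full-library screen;
    strongly_selected — fraction >= ``strong_fraction`` in at least
                        ``strong_screens`` independent screens (any library);
    significantly_enriched — >= ``enriched_clones`` clones in each of at
                        least ``enriched_screens`` independent screens.
    """

    dominant_fraction: float = 0.40
    strong_fraction: float = 0.10
    strong_screens: int = 2
    enriched_clones: int = 2
    enriched_screens: int = 2


def load_screen_counts(source: IO[str] | str,
                       libraries: Mapping[str, SH3Library] | None = None,
                       ) -> list[ScreenResult]:
    """Load a clone-count TSV into :class:`ScreenResult` objects.

    Required columns: screen_id, adam_id, library_id, sh3_id, clones.
    Optional: enrichment (one value per screen, ">" dialect allowed) and
    full_library (0/1, default 1).  If ``libraries`` is given, a clone of
    an SH3 excluded from the referenced library raises ``ValueError`` —
    a contamination signal, never silently dropped.
    """
    df = pd.read_csv(source, sep="\t", dtype={"clones": int})
    required = {"screen_id", "adam_id", "library_id", "sh3_id", "clones"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    screens = []
    for screen_id, grp in df.groupby("screen_id", sort=True):
        adams = grp["adam_id"].unique()
        if len(adams) != 1:
            raise ValueError(f"screen {screen_id!r} spans multiple ADAMs: {list(adams)}")
        lib_id = grp["library_id"].iloc[0]
        counts = dict(zip(grp["sh3_id"], grp["clones"].astype(int)))
        if libraries is not None and lib_id in libraries:
            bad = set(counts) & set(libraries[lib_id].excluded)
            if bad:
                raise ValueError(
                    f"screen {screen_id!r}: clones of excluded SH3(s) {sorted(bad)} "
                    f"in library {lib_id!r} (possible contamination)")
        enr = None
        if "enrichment" in grp.columns and pd.notna(grp["enrichment"].iloc[0]):
            enr = EnrichmentFactor.parse(grp["enrichment"].iloc[0])
        full = bool(grp["full_library"].iloc[0]) if "full_library" in grp.columns else True
        screens.append(ScreenResult(str(screen_id), str(adams[0]), str(lib_id),
                                    counts, enrichment=enr, full_library=full))
    return screens


def dominance_fraction(screen: ScreenResult, k: int) -> float:
    """Fraction of sequenced clones contributed by the k most-selected SH3s."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if screen.total_clones == 0:
        raise ValueError(f"screen {screen.screen_id!r} has no clones")
    # ties broken by SH3 id for reproducible top-k reporting; the fraction
    # itself is tie-invariant
    ranked = sorted(screen.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return sum(c for _, c in ranked[:k]) / screen.total_clones


def top_k_sh3(screen: ScreenResult, k: int) -> list[str]:
    ranked = sorted(screen.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [s for s, _ in ranked[:k]]


def classify_selection(screens: Sequence[ScreenResult],
                       thresholds: TierThresholds = TierThresholds(),
                       ) -> SelectionProfile:
    """Classify SH3 partners of one ADAM into the three selection tiers.

    Independent screens are distinct ``screen_id`` values.  The highest
    satisfied tier wins; by construction a dominant SH3 observed at a high
    fraction in one screen may lack the multi-screen support required for
    the lower tiers, so each criterion is evaluated independently.
    """
    if not screens:
        raise ValueError("no screens supplied")
    adams = {s.adam_id for s in screens}
    if len(adams) != 1:
        raise ValueError(f"screens span multiple ADAMs: {sorted(adams)}")
    adam_id = screens[0].adam_id

    sh3_ids = sorted({s for scr in screens for s in scr.counts})
    tier: dict[str, str] = {}
    evidence: dict[str, dict] = {}
    for sh3 in sh3_ids:
        fracs, clones, full_fracs = [], [], []
        for scr in screens:
            c = scr.counts.get(sh3, 0)
            if c == 0:
                continue
            f = c / scr.total_clones
            fracs.append(f)
            clones.append(c)
            if scr.full_library:
                full_fracs.append(f)
        dominant = any(f >= thresholds.dominant_fraction for f in full_fracs)
        strong = sum(f >= thresholds.strong_fraction for f in fracs) >= thresholds.strong_screens
        enriched = sum(c >= thresholds.enriched_clones for c in clones) >= thresholds.enriched_screens
        if dominant:
            t = "dominant"
        elif strong:
            t = "strongly_selected"
        elif enriched:
            t = "significantly_enriched"
        else:
            t = "none"
        tier[sh3] = t
        evidence[sh3] = {
            "max_fraction": max(fracs, default=0.0),
            "max_full_library_fraction": max(full_fracs, default=0.0),
            "screens_observed": len(fracs),
            "total_clones": sum(clones),
        }
    return SelectionProfile(adam_id, tier, evidence, thresholds)


def design_reduction_library(base: SH3Library, profile: SelectionProfile,
                             drop_tiers: Sequence[str] = ("dominant",),
                             library_id: str | None = None) -> SH3Library:
    """Exclude the top-tier binders from a library for the next screen.

    By default only dominant SH3s are dropped; pass
    ``drop_tiers=("dominant", "strongly_selected")`` for deeper reduction.
    Raises ``ValueError`` if the exclusion would empty the library.
    """
    to_drop = {s for t in drop_tiers for s in profile.in_tier(t)}
    excluded = base.excluded | to_drop
    remaining = {k: v for k, v in base.abundance.items() if k not in excluded}
    if not any(v > 0 for v in remaining.values()):
        raise ValueError("reduction would empty the library")
    if library_id is None:
        library_id = f"{base.library_id}-red{len(excluded)}"
    ab = dict(base.abundance)
    return SH3Library(library_id, ab, excluded)


def negative_control_diversity(screen: ScreenResult) -> tuple[int, int]:
    """(distinct SH3 count, total clones) — an unbiased control shows many
    distinct SH3s at low counts, e.g. 79 distinct among 119 clones."""
    distinct = sum(1 for c in screen.counts.values() if c >= 1)
    return distinct, screen.total_clones
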