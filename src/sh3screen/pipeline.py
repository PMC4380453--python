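"""End-to-end orchestration, bundled reference tables, consistency checks.

The package ships transcriptions of the published cross-tables: the six
printed ADAM cytosolic tails, the per-ADAM screening statistics (enrichment
factor, reduction-library count, sequenced clones, selected-domain totals)
and the tier assignments per ADAM/SH3 pair.  ADAM19 was screened but its
tail sequence is not printed; it is carried as "sequence unavailable" and
excluded from sequence-level steps.

``run_full_pipeline`` chains every stage on synthetic screens and arrays:
scan tails -> tile peptides -> simulate panning series -> classify tiers ->
simulate and quantify arrays -> cluster -> export.  Outputs embed the
config hash and seed, so equal configs give byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import pandas as pd

from . import array_quant, motif_scan, phage_selection, synthetic
from .motif_scan import ProteinTail
from .phage_selection import SH3Library, TierThresholds

log = logging.getLogger("sh3screen")

#: ADAMs covered by the bundled screen statistics, in table order.
SCREENED_ADAMS = ("ADAM8", "ADAM9", "ADAM10", "ADAM12", "ADAM15", "ADAM17", "ADAM19")

#: Screened ADAM whose tail sequence is not available.
SEQUENCE_UNAVAILABLE = ("ADAM19",)


@dataclass(frozen=True)
class PaperFixture:
    """Bundled reference data: tails, per-ADAM totals, tier table."""

    tails: tuple[ProteinTail, ...]
    table1: pd.DataFrame
    table2: pd.DataFrame

    def tail(self, adam_id: str) -> ProteinTail | None:
        for t in self.tails:
            if t.id == adam_id:
                return t
        return None

    def tiers_for(self, adam_id: str) -> dict[str, str]:
        sub = self.table2[self.table2["adam_id"] == adam_id]
        return dict(zip(sub["sh3_id"], sub["tier"]))


def load_fixture() -> PaperFixture:
    """Load the bundled tails and tables."""
    data = files("sh3screen.data")
    tails = tuple(motif_scan.parse_tails(str(data / "adam_tails.fasta")))
    table1 = pd.read_csv(str(data / "table1_totals.tsv"), sep="\t")
    table2 = pd.read_csv(str(data / "table2_tiers.tsv"), sep="\t")
    return PaperFixture(tails, table1, table2)


def check_fixture_consistency(fixture: PaperFixture) -> pd.DataFrame:
    """Cross-check: distinct tiered SH3s per ADAM vs the reported totals.

    Returns one row per ADAM with the tier-table count, the reported
    selected-domain total and a match flag.  Duplicate (adam, sh3) entries
    across tiers raise ``ValueError``.
    """
    t2 = fixture.table2
    dup = t2.duplicated(subset=["adam_id", "sh3_id"])
    if dup.any():
        pairs = t2.loc[dup, ["adam_id", "sh3_id"]].values.tolist()
        raise ValueError(f"duplicate tier entries: {pairs}")
    bad_tiers = set(t2["tier"]) - {"dominant", "strongly_selected", "significantly_enriched"}
    if bad_tiers:
        raise ValueError(f"unknown tier names: {sorted(bad_tiers)}")
    counts = t2.groupby("adam_id")["sh3_id"].nunique()
    rows = []
    for _, row in fixture.table1.iterrows():
        adam = row["adam_id"]
        n = int(counts.get(adam, 0))
        expected = int(row["selected_domains"])
        rows.append({"adam_id": adam, "tier_entries": n,
                     "reported_total": expected, "match": n == expected})
    extra = set(t2["adam_id"]) - set(fixture.table1["adam_id"])
    if extra:
        raise ValueError(f"tier table lists ADAMs absent from the totals table: {sorted(extra)}")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run (serialized into every report)."""

    out_dir: str = "sh3screen-out"
    seed: int = 42
    pattern_file: str | None = None  # None -> shipped defaults
    thresholds: TierThresholds = TierThresholds()
    gap_merge: int = 8
    clones_sequenced: int = 150
    panning_rounds: int = 2
    noise_cv: float = 0.1
    linkage_method: str = "average"
    adams: tuple[str, ...] = SCREENED_ADAMS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        # out_dir does not affect content, so it is not part of the hash:
        # equal hashes imply byte-identical outputs wherever they are written
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"# sh3screen config={config.config_hash} seed={config.seed}\n"


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage on the bundled tails plus synthetic experiments.

    Returns a summary dict (also written as ``summary.json``); all stage
    outputs are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = load_fixture()
    patterns = (motif_scan.load_patterns(config.pattern_file)
                if config.pattern_file else motif_scan.default_patterns())
    summary: dict = {"config": config.to_dict(), "config_hash": config.config_hash,
                     "stages": {}}

    # ---- stage 1: motif scan + clusters + peptides -------------------
    all_hits, all_clusters, all_peptides = [], [], []
    unavailable = []
    for adam in config.adams:
        tail = fixture.tail(adam)
        if tail is None:
            unavailable.append(adam)
            continue
        hits = motif_scan.scan_motifs(tail, patterns)
        clusters = motif_scan.find_clusters(hits, tail, gap_merge=config.gap_merge)
        all_hits.extend(hits)
        all_clusters.extend(clusters)
        for cluster in clusters:
            all_peptides.extend(motif_scan.tile_peptides(cluster, tail))
    (out / "motif_hits.tsv").write_text(_header(config) + motif_scan.hits_to_tsv(all_hits))
    (out / "proline_clusters.tsv").write_text(
        _header(config) + motif_scan.clusters_to_tsv(all_clusters))
    (out / "peptides.fasta").write_text(motif_scan.peptides_to_fasta(all_peptides))
    log.info("motif_scan: %d tails -> %d hits, %d clusters, %d peptides",
             len(config.adams) - len(unavailable), len(all_hits),
             len(all_clusters), len(all_peptides))
    summary["stages"]["motif_scan"] = {
        "tails_scanned": len(config.adams) - len(unavailable),
        "sequence_unavailable": unavailable,
        "hits": len(all_hits), "clusters": len(all_clusters),
        "peptides": len(all_peptides),
    }

    # ---- stage 2: simulated panning series + classification ----------
    library = phage_selection.default_library()
    profiles = {}
    screen_counts = {}
    for i, adam in enumerate(config.adams):
        tiers = fixture.tiers_for(adam)
        affinity = synthetic.profile_from_tiers(adam, tiers)
        cfg = synthetic.PanningConfig(
            rounds=config.panning_rounds, clones_sequenced=config.clones_sequenced,
            seed=config.seed + 10_000 * (i + 1))
        screens = synthetic.simulate_screen_series(
            library, affinity, cfg, thresholds=config.thresholds)
        profile = phage_selection.classify_selection(screens, config.thresholds)
        profiles[adam] = profile
        screen_counts[adam] = len(screens)
        log.info("phage_selection: %s -> %d screens, %d selected SH3s",
                 adam, len(screens), len(profile.selected))
    report = {
        adam: {
            "screens": screen_counts[adam],
            "thresholds": dataclasses.asdict(config.thresholds),
            "tiers": {t: p.in_tier(t)
                      for t in ("dominant", "strongly_selected", "significantly_enriched")},
        }
        for adam, p in profiles.items()
    }
    (out / "selection_profiles.json").write_text(
        json.dumps({"config_hash": config.config_hash, "seed": config.seed,
                    "profiles": report}, indent=2, sort_keys=True) + "\n")
    summary["stages"]["phage_selection"] = {
        adam: {"screens": screen_counts[adam], "selected": len(profiles[adam].selected)}
        for adam in profiles
    }

    # ---- stage 3: synthetic array + quantification + clustering ------
    probe_ids = sorted({s for adam in config.adams for s in fixture.tiers_for(adam)})
    peptide_names = [p.name for p in all_peptides]
    import numpy as np

    rng = np.random.default_rng(config.seed)
    truth = pd.DataFrame(0.0, index=peptide_names, columns=probe_ids)
    for probe in probe_ids:
        binders = rng.choice(len(peptide_names), size=max(1, len(peptide_names) // 6),
                             replace=False)
        truth.iloc[binders, truth.columns.get_loc(probe)] = rng.uniform(50, 400, binders.size)
    slides = synthetic.simulate_array(truth, noise_cv=config.noise_cv,
                                      seed=config.seed + 1)
    matrix = array_quant.quantify_slides(slides)
    normalized = array_quant.normalize_columns(matrix)
    row_tree = array_quant.cluster_matrix(normalized, "rows", method=config.linkage_method)
    col_tree = array_quant.cluster_matrix(normalized, "cols", method=config.linkage_method)
    (out / "signal_normalized.tsv").write_text(
        _header(config) + array_quant.export_tsv(normalized))
    array_quant.export_heatmap(normalized, str(out / "heatmap.cdt"),
                               row_tree=row_tree, col_tree=col_tree, fmt="cdt")
    log.info("array_quant: %d peptides x %d probes, %d all-background columns",
             len(normalized.peptides), len(normalized.probes),
             len(normalized.all_background))
    summary["stages"]["array_quant"] = {
        "peptides": len(normalized.peptides), "probes": len(normalized.probes),
        "all_background_columns": sorted(normalized.all_background),
    }

    # ---- stage 4: fixture consistency --------------------------------
    consistency = check_fixture_consistency(fixture)
    summary["stages"]["fixture_check"] = {
        "all_match": bool(consistency["match"].all()),
        "rows": consistency.to_dict(orient="records"),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
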