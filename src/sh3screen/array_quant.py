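"""Peptide-array quantification: background model, normalization, clustering.

A CelluSpot slide carries the tiled ADAM peptides spotted in triplicate
and is probed with one GST-SH3 domain.  The quantification chain is:

1. slide background = mean of the empty spots + 2 x their sample SD;
2. per peptide, average the three replicate spots and subtract the
   background, clipping negatives to zero;
3. scale each probe column so its strongest peptide signal equals 2
   (columns with no signal above background stay zero and are flagged);
4. cluster rows/columns by average-linkage agglomeration on
   1 - centered Pearson correlation and export a TreeView-compatible
   heat map (CDT/GTR/ATR), grayscale 0 -> white (background level),
   2 -> black (strongest binding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

STAGES = ("raw_mean", "bg_subtracted", "normalized")


@dataclass
class ArraySlide:
    """One probing: a slide of triplicate peptide spots plus empty spots.

    ``spots`` maps peptide name -> three raw replicate signals;
    ``probe_concentration`` (μg/ml) is metadata only — concentrations were
    chosen per probe to balance signal and are not corrected for.
    """

    slide_id: str
    probe_id: str
    spots: dict[str, list[float]]
    empty_signals: list[float]
    probe_concentration: float | None = None
    control: bool = False  # e.g. GST-only probing; excluded from clustering

    def __post_init__(self) -> None:
        for pep, reps in self.spots.items():
            if len(reps) != 3:
                raise ValueError(
                    f"slide {self.slide_id}: peptide {pep!r} has "
                    f"{len(reps)} replicate spots, expected 3")
            if any(r < 0 for r in reps):
                raise ValueError(f"slide {self.slide_id}: negative raw signal for {pep!r}")


@dataclass
class SignalMatrix:
    """Peptides x probes signal matrix at a named pipeline stage."""

    data: pd.DataFrame  # rows: peptide names, cols: probe ids
    stage: str
    all_background: frozenset[str] = frozenset()  # flagged all-zero columns
    clipped: tuple[tuple[str, str], ...] = ()     # (peptide, probe) clipped at 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def peptides(self) -> list[str]:
        return list(self.data.index)

    @property
    def probes(self) -> list[str]:
        return list(self.data.columns)


def estimate_background(slide: ArraySlide, sd_factor: float = 2.0,
                        ddof: int = 1) -> float:
    """Slide background: mean of empty spots + ``sd_factor`` x sample SD."""
    empties = np.asarray(slide.empty_signals, dtype=float)
    if empties.size < 2:
        raise ValueError(
            f"slide {slide.slide_id}: need >=2 empty spots to estimate background")
    return float(empties.mean() + sd_factor * empties.std(ddof=ddof))


def average_and_subtract(slide: ArraySlide, background: float) -> SignalMatrix:
    """Triplicate means minus background, clipped at 0 (one probe column)."""
    values, clipped = {}, []
    for pep, reps in sorted(slide.spots.items()):
        v = float(np.mean(reps)) - background
        if v < 0:
            clipped.append((pep, slide.probe_id))
            v = 0.0
        values[pep] = v
    df = pd.DataFrame({slide.probe_id: values})
    return SignalMatrix(df, "bg_subtracted", clipped=tuple(clipped))


def quantify_slides(slides: Sequence[ArraySlide],
                    sd_factor: float = 2.0) -> SignalMatrix:
    """Full per-slide background + subtraction across a slide set.

    Every slide contributes one probe column; peptides must agree across
    slides (missing peptides raise ``ValueError``).
    """
    if not slides:
        raise ValueError("no slides supplied")
    cols, clipped = [], []
    peptide_sets = {frozenset(s.spots) for s in slides}
    if len(peptide_sets) != 1:
        raise ValueError("slides carry different peptide sets")
    for slide in slides:
        bg = estimate_background(slide, sd_factor=sd_factor)
        col = average_and_subtract(slide, bg)
        cols.append(col.data)
        clipped.extend(col.clipped)
    df = pd.concat(cols, axis=1)
    return SignalMatrix(df, "bg_subtracted", clipped=tuple(clipped))


def normalize_columns(matrix: SignalMatrix, target: float = 2.0) -> SignalMatrix:
    """Scale each probe column so its maximum equals ``target``.

    All-zero columns (nothing above background) are left at zero and
    flagged; negative inputs indicate a missing upstream clipping step and
    raise ``ValueError``.
    """
    if matrix.stage != "bg_subtracted":
        raise ValueError(f"normalize_columns expects stage bg_subtracted, got {matrix.stage}")
    if (matrix.data.values < 0).any():
        raise ValueError("negative values: background clipping must happen upstream")
    df = matrix.data.copy()
    flagged = []
    for col in df.columns:
        m = df[col].max()
        if m > 0:
            df[col] = df[col] * (target / m)
        else:
            flagged.append(col)
    return SignalMatrix(df, "normalized", all_background=frozenset(flagged),
                        clipped=matrix.clipped)


def correlation_distance(matrix: SignalMatrix, axis: str = "rows") -> np.ndarray:
    """Pairwise 1 - centered Pearson correlation along rows or columns.

    A constant (zero-variance) row/column has undefined correlation; its
    distance to everything is defined as the maximum, 2.0.
    """
    X = matrix.data.values if axis == "rows" else matrix.data.values.T
    n = X.shape[0]
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    D = np.full((n, n), 2.0)
    np.fill_diagonal(D, 0.0)
    ok = norms > 0
    if ok.any():
        C = centered[ok] @ centered[ok].T
        C /= np.outer(norms[ok], norms[ok])
        idx = np.where(ok)[0]
        D[np.ix_(idx, idx)] = 1.0 - np.clip(C, -1.0, 1.0)
        D[idx, idx] = 0.0
    return D


@dataclass
class ClusterResult:
    """Linkage matrix (scipy format) plus the reordered leaf labels."""

    linkage: np.ndarray
    leaves: list[str]
    axis: str
    degenerate: tuple[str, ...] = ()  # zero-variance leaves, distance fixed at 2


def cluster_matrix(matrix: SignalMatrix, axis: str = "rows",
                   method: str = "average") -> ClusterResult:
    """Agglomerative clustering on 1 - centered Pearson distance.

    Average linkage by default (the common Cluster 3 configuration);
    scipy's deterministic agglomeration gives reproducible tie-breaking.
    """
    if matrix.stage != "normalized":
        raise ValueError("cluster_matrix expects a normalized matrix")
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    labels = matrix.peptides if axis == "rows" else matrix.probes
    if len(labels) < 2:
        raise ValueError("need >=2 leaves to cluster")
    X = matrix.data.values if axis == "rows" else matrix.data.values.T
    degenerate = tuple(lab for lab, row in zip(labels, X) if np.ptp(row) == 0)
    D = correlation_distance(matrix, axis=axis)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(Z, [labels[i] for i in order], axis, degenerate)


def _tree_lines(Z: np.ndarray, leaves_prefix: str, node_prefix: str) -> list[str]:
    """GTR/ATR lines: NODE, child, child, score (= 1 - merge distance)."""
    n = Z.shape[0] + 1

    def name(i: int) -> str:
        return f"{leaves_prefix}{i}X" if i < n else f"{node_prefix}{i - n + 1}X"

    return [
        f"{node_prefix}{k + 1}X\t{name(int(a))}\t{name(int(b))}\t{1.0 - h:.6f}"
        for k, (a, b, h, _) in enumerate(Z)
    ]


def export_tsv(matrix: SignalMatrix) -> str:
    """Plain TSV of the matrix (round-trips bit-exactly via repr floats)."""
    out = ["peptide\t" + "\t".join(matrix.probes)]
    for pep in matrix.peptides:
        row = matrix.data.loc[pep]
        out.append(pep + "\t" + "\t".join(repr(float(v)) for v in row))
    return "\n".join(out) + "\n"


def parse_tsv(text: str, stage: str = "normalized") -> SignalMatrix:
    rows = [line.split("\t") for line in text.strip().split("\n")]
    probes = rows[0][1:]
    data = {r[0]: [float(v) for v in r[1:]] for r in rows[1:]}
    df = pd.DataFrame.from_dict(data, orient="index", columns=probes)
    return SignalMatrix(df, stage)


def export_cdt(matrix: SignalMatrix, row_tree: ClusterResult | None = None,
               col_tree: ClusterResult | None = None) -> dict[str, str]:
    """Java TreeView export: CDT (+ GTR/ATR when trees are given).

    Leaf order in the CDT follows the cluster orderings; GTR/ATR node
    scores follow the TreeView convention of similarity = 1 - distance.
    """
    peptides = row_tree.leaves if row_tree else matrix.peptides
    probes = col_tree.leaves if col_tree else matrix.probes
    row_pos = {p: i for i, p in enumerate(matrix.peptides)}
    col_pos = {p: i for i, p in enumerate(matrix.probes)}

    header = ["GID", "UNIQID", "NAME", "GWEIGHT"] + list(probes)
    lines = ["\t".join(header)]
    lines.append("\t".join(["EWEIGHT", "", "", ""] + ["1"] * len(probes)))
    for pep in peptides:
        gid = f"GENE{row_pos[pep]}X"
        vals = [f"{matrix.data.loc[pep, pr]:.6f}" for pr in probes]
        lines.append("\t".join([gid, pep, pep, "1"] + vals))
    files = {"cdt": "\n".join(lines) + "\n"}
    if row_tree is not None:
        files["gtr"] = "\n".join(_tree_lines(row_tree.linkage, "GENE", "NODE")) + "\n"
    if col_tree is not None:
        files["atr"] = "\n".join(_tree_lines(col_tree.linkage, "ARRY", "NODE")) + "\n"
    return files


def export_heatmap(matrix: SignalMatrix, path: str,
                   row_tree: ClusterResult | None = None,
                   col_tree: ClusterResult | None = None,
                   fmt: str = "tsv") -> list[str]:
    """Write the matrix in the requested format; returns written paths.

    ``tsv`` — plain matrix; ``cdt`` — TreeView CDT/GTR/ATR set; ``png`` —
    grayscale heat map (0 white = background level, 2 black = strongest).
    """
    written = []
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(export_tsv(matrix))
        written.append(path)
    elif fmt == "cdt":
        base = path[:-4] if path.endswith(".cdt") else path
        for ext, text in export_cdt(matrix, row_tree, col_tree).items():
            p = f"{base}.{ext}"
            with open(p, "w") as fh:
                fh.write(text)
            written.append(p)
    elif fmt == "png":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        peptides = row_tree.leaves if row_tree else matrix.peptides
        probes = col_tree.leaves if col_tree else matrix.probes
        img = matrix.data.loc[peptides, probes].values
        fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(probes)),
                                        max(4, 0.25 * len(peptides))))
        ax.imshow(img, cmap="Greys", vmin=0.0, vmax=2.0, aspect="auto")
        ax.set_xticks(range(len(probes)), probes, rotation=90, fontsize=6)
        ax.set_yticks(range(len(peptides)), peptides, fontsize=6)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return written


def load_spot_table(spots_source: IO[str] | str,
                    empties_source: IO[str] | str) -> list[ArraySlide]:
    """Build slides from spot/empty TSVs.

    Spot columns: slide_id, probe_id, probe_conc, peptide, replicate,
    signal (+ optional control 0/1).  Empty columns: slide_id, signal.
    """
    spots = pd.read_csv(spots_source, sep="\t")
    empties = pd.read_csv(empties_source, sep="\t")
    slides = []
    for slide_id, grp in spots.groupby("slide_id", sort=True):
        probe = grp["probe_id"].iloc[0]
        conc = float(grp["probe_conc"].iloc[0]) if "probe_conc" in grp.columns else None
        control = bool(grp["control"].iloc[0]) if "control" in grp.columns else False
        spot_map: dict[str, list[float]] = {}
        for pep, pgrp in grp.groupby("peptide"):
            spot_map[pep] = list(pgrp.sort_values("replicate")["signal"].astype(float))
        empty = list(empties.loc[empties["slide_id"] == slide_id, "signal"].astype(float))
        slides.append(ArraySlide(str(slide_id), str(probe), spot_map, empty,
                                 probe_concentration=conc, control=control))
    return slides
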