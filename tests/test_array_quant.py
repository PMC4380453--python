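import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sh3screen as s
from sh3screen.array_quant import (
    correlation_distance,
    export_cdt,
    export_tsv,
    parse_tsv,
)

from conftest import naive_average_linkage


def make_slide(spots, empties, probe="SH3-A", slide_id="sl1"):
    return s.ArraySlide(slide_id, probe, spots, empties)


def random_matrix(rng, n=6, m=5, stage="bg_subtracted"):
    data = rng.uniform(0, 100, (n, m))
    df = pd.DataFrame(data, index=[f"p{i}" for i in range(n)],
                      columns=[f"c{j}" for j in range(m)])
    return s.SignalMatrix(df, stage)


class TestBackground:
    def test_constant_empties_give_their_value(self):
        slide = make_slide({"p": [1, 2, 3]}, [5.0] * 33)
        assert s.estimate_background(slide) == 5.0

    def test_two_empties_closed_form(self):
        slide = make_slide({"p": [1, 2, 3]}, [4.0, 6.0])
        assert s.estimate_background(slide) == pytest.approx(5 + 2 * math.sqrt(2))

    def test_fewer_than_two_empties_rejected(self):
        slide = make_slide({"p": [1, 2, 3]}, [4.0])
        with pytest.raises(ValueError, match="empty spots"):
            s.estimate_background(slide)

    def test_monte_carlo_recovers_mu_plus_two_sigma(self):
        # 1,000 seeded slides of 33 Normal(100, 10) empties: the estimator
        # mean should sit near mu + 2*sigma = 120 within sampling error
        mu, sigma = 100.0, 10.0
        estimates = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            slide = make_slide({"p": [1, 2, 3]},
                               list(rng.normal(mu, sigma, 33)))
            estimates.append(s.estimate_background(slide))
        # SE of the mean estimate across runs is ~0.08; allow 4 SE plus the
        # small-sample bias of the SD estimate (~ -0.8% of sigma)
        assert np.mean(estimates) == pytest.approx(mu + 2 * sigma, abs=1.0)


class TestAverageAndSubtract:
    def test_triplicate_mean_minus_background(self):
        slide = make_slide({"p": [10, 12, 14]}, [0.0] * 33)
        mat = s.average_and_subtract(slide, background=6.0)
        assert mat.data.loc["p", "SH3-A"] == pytest.approx(6.0)
        assert mat.stage == "bg_subtracted"

    def test_below_background_clipped_and_logged(self):
        slide = make_slide({"p": [1, 1, 1]}, [0.0] * 33)
        mat = s.average_and_subtract(slide, background=6.0)
        assert mat.data.loc["p", "SH3-A"] == 0.0
        assert ("p", "SH3-A") in mat.clipped

    def test_replicate_order_irrelevant(self):
        a = s.average_and_subtract(make_slide({"p": [10, 12, 14]}, [0] * 3), 6.0)
        b = s.average_and_subtract(make_slide({"p": [14, 10, 12]}, [0] * 3), 6.0)
        assert a.data.equals(b.data)

    def test_missing_replicate_rejected_with_name(self):
        with pytest.raises(ValueError, match="pepX"):
            make_slide({"pepX": [10, 12]}, [0] * 33)


class TestNormalizeColumns:
    def test_maximum_maps_to_two(self):
        df = pd.DataFrame({"c": [0.0, 3.0, 6.0]}, index=list("abc"))
        out = s.normalize_columns(s.SignalMatrix(df, "bg_subtracted"))
        assert list(out.data["c"]) == [0.0, 1.0, 2.0]

    def test_all_zero_column_flagged(self):
        df = pd.DataFrame({"c": [0.0, 0.0]}, index=list("ab"))
        out = s.normalize_columns(s.SignalMatrix(df, "bg_subtracted"))
        assert list(out.data["c"]) == [0.0, 0.0]
        assert out.all_background == {"c"}

    def test_single_peptide_column(self):
        df = pd.DataFrame({"c": [2.0]}, index=["a"])
        out = s.normalize_columns(s.SignalMatrix(df, "bg_subtracted"))
        assert out.data.loc["a", "c"] == 2.0

    def test_negative_input_rejected(self):
        df = pd.DataFrame({"c": [-1.0, 5.0]}, index=list("ab"))
        with pytest.raises(ValueError, match="clipping"):
            s.normalize_columns(s.SignalMatrix(df, "bg_subtracted"))

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), c=st.floats(0.01, 100))
    def test_scale_equivariance_and_idempotence(self, seed, c):
        rng = np.random.default_rng(seed)
        mat = random_matrix(rng)
        out = s.normalize_columns(mat)
        scaled = s.SignalMatrix(mat.data * c, "bg_subtracted")
        out_scaled = s.normalize_columns(scaled)
        assert np.allclose(out.data.values, out_scaled.data.values)
        again = s.normalize_columns(s.SignalMatrix(out.data, "bg_subtracted"))
        assert np.allclose(out.data.values, again.data.values)
        assert (out.data.values >= 0).all() and (out.data.values <= 2).all()
        assert np.allclose(out.data.max(axis=0), 2.0)

    def test_whole_slide_scale_invariance(self):
        # multiplying raw signals and empties of a slide by c > 0 leaves the
        # normalized matrix unchanged
        rng = np.random.default_rng(7)
        truth = pd.DataFrame(rng.uniform(0, 300, (8, 4)),
                             index=[f"p{i}" for i in range(8)],
                             columns=[f"c{j}" for j in range(4)])
        slides = s.simulate_array(truth, noise_cv=0.1, seed=3)
        scaled = [s.ArraySlide(sl.slide_id, sl.probe_id,
                               {p: [5.0 * v for v in r] for p, r in sl.spots.items()},
                               [5.0 * v for v in sl.empty_signals])
                  for sl in slides]
        a = s.normalize_columns(s.quantify_slides(slides))
        b = s.normalize_columns(s.quantify_slides(scaled))
        assert np.allclose(a.data.values, b.data.values)


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[0, 1, 2], [0, 1, 2], [2, 1, 0]],
                          index=list("abc"), columns=list("xyz"), dtype=float)
        mat = s.SignalMatrix(df, "normalized")
        res = s.cluster_matrix(mat, "rows")
        assert res.linkage[0, 2] == pytest.approx(0.0)
        first = {res.leaves.index("a"), res.leaves.index("b")}
        assert first in ({0, 1}, {1, 2})  # adjacent after reordering

    def test_anticorrelated_rows_at_distance_two(self):
        df = pd.DataFrame([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
                          index=list("ab"), columns=list("xyz"))
        D = correlation_distance(s.SignalMatrix(df, "normalized"), "rows")
        assert D[0, 1] == pytest.approx(2.0)

    def test_constant_row_distance_defined_as_maximum(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                          index=list("ab"), columns=list("xyz"))
        mat = s.SignalMatrix(df, "normalized")
        D = correlation_distance(mat, "rows")
        assert D[0, 1] == 2.0
        res = s.cluster_matrix(mat, "rows")
        assert res.degenerate == ("a",)

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_heights_match_naive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_matrix(rng, n=10, m=8, stage="normalized")
        res = s.cluster_matrix(mat, "rows")
        D = correlation_distance(mat, "rows")
        assert np.allclose(sorted(res.linkage[:, 2]), naive_average_linkage(D))

    def test_heights_non_decreasing_and_label_invariant(self):
        rng = np.random.default_rng(11)
        mat = random_matrix(rng, n=8, m=6, stage="normalized")
        res = s.cluster_matrix(mat, "rows")
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        relabeled = s.SignalMatrix(
            mat.data.set_axis([f"q{i}" for i in range(8)], axis=0), "normalized")
        res2 = s.cluster_matrix(relabeled, "rows")
        assert np.allclose(res.linkage[:, 2], res2.linkage[:, 2])

    def test_single_leaf_rejected(self):
        df = pd.DataFrame({"c": [1.0, 2.0]}, index=list("ab"))
        with pytest.raises(ValueError, match=">=2 leaves"):
            s.cluster_matrix(s.SignalMatrix(df, "normalized"), "cols")


class TestExport:
    def _normalized(self, rng, n=4, m=3):
        mat = random_matrix(rng, n=n, m=m)
        return s.normalize_columns(mat)

    def test_tsv_round_trip_bit_exact(self):
        mat = self._normalized(np.random.default_rng(0))
        again = parse_tsv(export_tsv(mat))
        assert again.data.equals(mat.data)

    def test_cdt_gtr_structure(self):
        df = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=list("ab"),
                          columns=list("xy"))
        mat = s.SignalMatrix(df, "normalized")
        row_tree = s.cluster_matrix(mat, "rows")
        files = export_cdt(mat, row_tree=row_tree)
        cdt_lines = files["cdt"].strip().split("\n")
        assert len(cdt_lines) == 4  # header + EWEIGHT + 2 data rows
        assert cdt_lines[0].split("\t")[:4] == ["GID", "UNIQID", "NAME", "GWEIGHT"]
        gtr_lines = files["gtr"].strip().split("\n")
        assert len(gtr_lines) == 1
        node, left, right, score = gtr_lines[0].split("\t")
        assert node == "NODE1X" and {left, right} == {"GENE0X", "GENE1X"}
        assert float(score) == pytest.approx(1.0 - row_tree.linkage[0, 2])

    def test_cdt_leaf_order_follows_clustering(self):
        mat = self._normalized(np.random.default_rng(5), n=6, m=4)
        row_tree = s.cluster_matrix(mat, "rows")
        files = export_cdt(mat, row_tree=row_tree)
        names = [line.split("\t")[1] for line in files["cdt"].strip().split("\n")[2:]]
        assert names == row_tree.leaves

    def test_unknown_format_rejected(self, tmp_path):
        mat = self._normalized(np.random.default_rng(1))
        with pytest.raises(ValueError, match="unknown export format"):
            s.export_heatmap(mat, str(tmp_path / "x"), fmt="xlsx")

    def test_heatmap_files_written(self, tmp_path):
        mat = self._normalized(np.random.default_rng(2), n=5, m=4)
        rt = s.cluster_matrix(mat, "rows")
        ct = s.cluster_matrix(mat, "cols")
        written = s.export_heatmap(mat, str(tmp_path / "m.cdt"), rt, ct, fmt="cdt")
        assert sorted(p.rsplit(".", 1)[1] for p in written) == ["atr", "cdt", "gtr"]
        tsv = s.export_heatmap(mat, str(tmp_path / "m.tsv"), fmt="tsv")
        assert (tmp_path / "m.tsv").exists() and tsv == [str(tmp_path / "m.tsv")]
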