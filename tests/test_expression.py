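import math

import numpy as np
import pandas as pd
import pytest

from mirseedscan.expression_validation import (
    call_cleavage,
    fold_change_ddct,
    mirna_target_correlation,
    normalization_factor,
    rapcr_profiles_from_ct,
    rapcr_reduction,
)
from mirseedscan.synthetic_data import (
    gen_expression_tables,
    gen_rapcr_tables,
)


def _ct_frame(rows):
    return pd.DataFrame(
        rows, columns=["genotype", "stage", "gene_id", "replicate", "ct"]
    )


class TestNormalization:
    def test_equal_ct_gives_unit_factor(self):
        rows = [
            ("g1", s, "ref", 1, 20.0) for s in ("35DAF", "45DAF", "55DAF")
        ]
        out = normalization_factor(_ct_frame(rows))
        assert np.allclose(out["factor"], 1.0)

    def test_uniform_shift_halves_factor(self):
        rows = []
        for s, shift in (("a", 0.0), ("b", 1.0)):
            for ref in ("r1", "r2", "r3"):
                rows.append(("g", s, ref, 1, 20.0 + shift))
        out = normalization_factor(_ct_frame(rows)).set_index("stage")
        # sample b: every reference +1 Ct relative to the gene means
        ratio = out.loc["b", "factor"] / out.loc["a", "factor"]
        assert ratio == pytest.approx(0.5)

    def test_mixed_shifts_geometric_mean(self):
        rows = []
        for s, shifts in (("a", (0.0, 0.0)), ("b", (2.0, 0.0))):
            for ref, sh in zip(("r1", "r2"), shifts):
                rows.append(("g", s, ref, 1, 20.0 + sh))
        out = normalization_factor(_ct_frame(rows)).set_index("stage")
        ratio = out.loc["b", "factor"] / out.loc["a", "factor"]
        assert ratio == pytest.approx(2.0 ** -1)

    def test_missing_reference_errors(self):
        rows = [("g", "a", "r1", 1, 20.0), ("g", "b", "r2", 1, 20.0)]
        with pytest.raises(ValueError, match="missing reference"):
            normalization_factor(_ct_frame(rows))


class TestFoldChange:
    def _tables(self, target_shift):
        refs = _ct_frame(
            [(g, s, r, 1, 18.0) for g in ("X",) for s in ("c", "t")
             for r in ("r1", "r2")]
        )
        tgt = _ct_frame(
            [("X", "c", "gene", 1, 24.0), ("X", "t", "gene", 1, 24.0 + target_shift)]
        )
        return tgt, refs

    def test_calibrator_sample_is_unity(self):
        tgt, refs = self._tables(0.0)
        folds = fold_change_ddct(tgt, refs, ("X", "c"))
        assert all(f.fold == pytest.approx(1.0) for f in folds)

    def test_ddct_minus_two_gives_fourfold(self):
        tgt, refs = self._tables(-2.0)
        folds = {f.stage: f.fold for f in fold_change_ddct(tgt, refs, ("X", "c"))}
        assert folds["t"] == pytest.approx(4.0)

    def test_large_planted_fold_recovered(self):
        # ddCt = -log2(58.82) ~ -5.88
        tgt, refs = self._tables(-math.log2(58.82))
        folds = {f.stage: f.fold for f in fold_change_ddct(tgt, refs, ("X", "c"))}
        assert folds["t"] == pytest.approx(58.82, rel=1e-9)

    def test_common_ct_shift_cancels(self):
        """Shifting every Ct of one sample (targets and references alike)
        leaves fold changes unchanged."""
        tgt, refs = self._tables(-2.0)
        tgt2 = tgt.copy()
        refs2 = refs.copy()
        mask_t = tgt2["stage"] == "t"
        tgt2.loc[mask_t, "ct"] += 3.0
        refs2.loc[refs2["stage"] == "t", "ct"] += 3.0
        f1 = {f.stage: f.fold for f in fold_change_ddct(tgt, refs, ("X", "c"))}
        f2 = {f.stage: f.fold for f in fold_change_ddct(tgt2, refs2, ("X", "c"))}
        assert f1["t"] == pytest.approx(f2["t"])

    def test_missing_calibrator_errors(self):
        tgt, refs = self._tables(0.0)
        with pytest.raises(ValueError, match="calibrator"):
            fold_change_ddct(tgt, refs, ("X", "zz"))

    def test_replicate_spread_propagates(self):
        refs = _ct_frame([("X", s, "r1", 1, 18.0) for s in ("c", "t")])
        tgt = _ct_frame(
            [("X", "c", "g", r, 24.0) for r in (1, 2, 3)]
            + [("X", "t", "g", 1, 21.9), ("X", "t", "g", 2, 22.0),
               ("X", "t", "g", 3, 22.1)]
        )
        folds = {f.stage: f for f in fold_change_ddct(tgt, refs, ("X", "c"))}
        assert folds["t"].fold == pytest.approx(4.0, rel=1e-6)
        assert folds["t"].se_log2 == pytest.approx(0.1, rel=1e-6)
        assert folds["c"].se_log2 == 0.0


class TestRaPcr:
    def test_eighty_percent_reduction(self):
        p = rapcr_reduction("t", "g", "s", 1.0, 0.2, 1.0)
        assert p.reduction_pct == pytest.approx(80.0)

    def test_equal_quantities_zero_reduction(self):
        assert rapcr_reduction("t", "g", "s", 1.0, 1.0, 1.0).reduction_pct == 0.0

    def test_extreme_reduction_band(self):
        p = rapcr_reduction("t", "g", "s", 1.0, 0.0094, 1.0)
        assert p.reduction_pct == pytest.approx(99.06)

    def test_rescaling_invariance(self):
        a = rapcr_reduction("t", "g", "s", 0.5, 0.1, 0.8)
        b = rapcr_reduction("t", "g", "s", 5.0, 1.0, 8.0)
        assert a.reduction_pct == pytest.approx(b.reduction_pct)

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            rapcr_reduction("t", "g", "s", 1.0, 0.0, 1.0)

    def test_cleavage_calls(self):
        def prof(red, stage):
            return rapcr_reduction("t", "g", stage, 1.0, 1.0 - red / 100, 1.0)

        ok = [prof(r, f"s{i}") for i, r in enumerate((80, 60, 90, 70))]
        assert call_cleavage(ok)[1] == "cleaved"
        mixed = [prof(r, f"s{i}") for i, r in enumerate((80, -5, 90, 70))]
        assert call_cleavage(mixed)[1] == "not_cleaved"

    def test_profiles_from_ct_roundtrip(self):
        ra, truth = gen_rapcr_tables(
            transcripts=["tx1", "tx2"], noise_sd_ct=0.0, seed=3
        )
        profiles = rapcr_profiles_from_ct(ra)
        for p in profiles:
            assert p.reduction_pct == pytest.approx(
                truth.planted_reductions[p.transcript_id], abs=1e-6
            )


class TestCorrelation:
    def test_perfect_anti_rank(self):
        r, call = mirna_target_correlation([4, 3, 2, 1], [1, 2, 3, 4], "spearman")
        assert r == pytest.approx(-1.0) and call == "negative"

    def test_identical_series(self):
        r, call = mirna_target_correlation([1, 2, 3, 4], [1, 2, 3, 4], "pearson")
        assert r == pytest.approx(1.0) and call == "positive"

    def test_constant_series_na(self):
        with pytest.warns(UserWarning):
            r, call = mirna_target_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and call == "NA"


class TestParameterRecovery:
    def test_fold_changes_recovered_within_15pct(self):
        """200 genes, noise SD 0.1 Ct: >=95% of planted fold changes come
        back within 15%."""
        rng = np.random.default_rng(13)
        genes = [f"gene{i:03d}" for i in range(200)]
        spec = {}
        for g in genes:
            for geno in ("NRC7", "NRC37"):
                for stage in ("45DAF", "55DAF", "65DAF"):
                    spec[(geno, stage, g)] = float(2.0 ** rng.uniform(-4, 6))
        tgt, refs, truth = gen_expression_tables(
            genes=genes, fold_spec=spec, noise_sd_ct=0.1, seed=3
        )
        folds = fold_change_ddct(tgt, refs, ("NRC7", "35DAF"))
        rel_ok = []
        for f in folds:
            want = truth.planted_fold_changes[(f.genotype, f.stage, f.gene_id)]
            rel_ok.append(abs(f.fold - want) / want <= 0.15)
        assert sum(rel_ok) / len(rel_ok) >= 0.95

    def test_cleavage_labels_recovered(self):
        """Planted cleavage fraction 0.7, noise SD 0.1 Ct: overall calls
        match planted labels for >=95% of 200 transcripts."""
        tids = [f"tx{i:03d}" for i in range(200)]
        ra, truth = gen_rapcr_tables(
            transcripts=tids, cleaved_fraction=0.7, noise_sd_ct=0.1, seed=5
        )
        profiles = rapcr_profiles_from_ct(ra)
        by_tid = {}
        for p in profiles:
            by_tid.setdefault(p.transcript_id, []).append(p)
        correct = 0
        for tid, ps in by_tid.items():
            _, overall = call_cleavage(ps)
            correct += (overall == "cleaved") == truth.planted_cleaved[tid]
        assert correct / len(tids) >= 0.95

    def test_anticorrelation_sign_recovered(self):
        """Planted anticorrelated miRNA/target pairs at log-fold noise SD
        0.2: sign recovered for >=90% of 200 pairs."""
        rng = np.random.default_rng(17)
        recovered = 0
        n_pairs = 200
        for _ in range(n_pairs):
            base = np.array([3.0, 2.0, 1.0, 0.0])  # log2 folds across stages
            mir = 2.0 ** (base + rng.normal(0, 0.2, 4))
            tgt = 2.0 ** (-base + rng.normal(0, 0.2, 4))
            r, call = mirna_target_correlation(mir, tgt, "pearson")
            recovered += call == "negative"
        assert recovered / n_pairs >= 0.90
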