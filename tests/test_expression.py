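"""2^-ddCt fold changes and Kruskal-Wallis significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famdiv.expression import (ddct_fold_changes, kruskal_wallis,
                               load_ct_table, relative_expression)
from famdiv.simulate import CtDesign, SimulationConfig, simulate_ct

from oracles import kruskal_h_oracle

REFS = ["actin", "ef1a"]


def _ct_table(target_shift=0.0, ref_shift=0.0, plate_offset=0.0,
              swap_labels=False):
    """Noise-free two-treatment panel: 3 bio reps, 2 tech reps, 2 refs."""
    rows = []
    for treatment in ("deficient", "control"):
        shift = target_shift if treatment == "deficient" else 0.0
        rshift = ref_shift if treatment == "deficient" else 0.0
        label = treatment
        if swap_labels:
            label = "control" if treatment == "deficient" else "deficient"
        for bio in (1, 2, 3):
            for tech in (1, 2):
                rows.append(dict(sample=f"x{bio}", gene="tgt", tissue="leaf",
                                 timepoint=14, treatment=label, bio_rep=bio,
                                 tech_rep=tech, ct=24.0 + shift + plate_offset))
                for ref, base in zip(REFS, (19.0, 21.0)):
                    rows.append(dict(sample=f"x{bio}", gene=ref, tissue="leaf",
                                     timepoint=14, treatment=label, bio_rep=bio,
                                     tech_rep=tech, ct=base + rshift + plate_offset))
    return pd.DataFrame(rows)


class TestDdct:
    def test_zero_ddct_gives_fold_one(self):
        res = ddct_fold_changes(_ct_table(0.0), "tgt", REFS, "leaf", 14)
        assert np.allclose(res.folds["deficient"], 1.0)

    def test_one_cycle_lower_doubles(self):
        res = ddct_fold_changes(_ct_table(-1.0), "tgt", REFS, "leaf", 14)
        assert np.allclose(res.folds["deficient"], 2.0)

    def test_calibrator_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        df = _ct_table(0.0)
        df["ct"] += rng.normal(0, 0.2, size=len(df))
        res = ddct_fold_changes(df, "tgt", REFS, "leaf", 14)
        gm = np.exp(np.mean(np.log(res.folds["control"])))
        assert gm == pytest.approx(1.0, abs=1e-12)

    def test_plate_offset_invariance(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.2, size=len(_ct_table()))
        a = _ct_table(-2.0)
        b = _ct_table(-2.0, plate_offset=3.7)
        a["ct"] += noise
        b["ct"] += noise
        ra = ddct_fold_changes(a, "tgt", REFS, "leaf", 14)
        rb = ddct_fold_changes(b, "tgt", REFS, "leaf", 14)
        assert np.allclose(ra.folds["deficient"], rb.folds["deficient"])

    def test_label_swap_inverts_folds(self):
        # swapping which group is the calibrator inverts the reported fold
        ra = ddct_fold_changes(_ct_table(-2.0), "tgt", REFS, "leaf", 14)
        rb = ddct_fold_changes(_ct_table(-2.0, swap_labels=True), "tgt",
                               REFS, "leaf", 14)
        assert np.allclose(ra.folds["deficient"], 1 / rb.folds["deficient"])
        assert ra.mean_fold["deficient"] == pytest.approx(4.0)
        assert rb.mean_fold["deficient"] == pytest.approx(0.25)

    def test_reference_shift_cancels(self):
        # shifting target and references together leaves folds at 1
        res = ddct_fold_changes(_ct_table(1.5, ref_shift=1.5), "tgt",
                                REFS, "leaf", 14)
        assert np.allclose(res.folds["deficient"], 1.0)

    def test_missing_reference_rejected(self):
        df = _ct_table()
        df.loc[df["gene"] == "actin", "ct"] = np.nan
        with pytest.raises(ValueError, match="reference gene"):
            ddct_fold_changes(df, "tgt", REFS, "leaf", 14)

    def test_undetected_target_reported(self):
        df = _ct_table()
        df.loc[(df["gene"] == "tgt") & (df["treatment"] == "deficient"), "ct"] = np.nan
        res = ddct_fold_changes(df, "tgt", REFS, "leaf", 14)
        assert res.not_detected == ["deficient"]

    def test_simulated_not_detected_propagates(self):
        cfg = SimulationConfig(seed=3)
        ct = simulate_ct(cfg)
        results = relative_expression(ct, ["pht_repressed"], REFS)
        root = [r for r in results if r.tissue == "root"]
        assert root and all(r.not_detected for r in root)

    def test_recovers_planted_folds_on_average(self):
        """Mean recovered fold over repeated simulations within 15% of truth."""
        cfg = SimulationConfig(seed=5)
        truth = cfg.ct_design.fold_changes
        est = {k: [] for k, v in truth.items() if v is not None}
        for rep in range(15):
            rng = np.random.default_rng(1000 + rep)
            ct = simulate_ct(cfg, rng)
            for (gene, tissue, tp), fold in truth.items():
                if fold is None:
                    continue
                r = ddct_fold_changes(ct, gene, REFS, tissue, tp)
                est[(gene, tissue, tp)].append(r.mean_fold["deficient"])
        for key, vals in est.items():
            assert np.mean(vals) == pytest.approx(truth[key], rel=0.15)


class TestKruskal:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_hand_rank_formula(self):
        g1, g2 = [1.2, 3.4, 2.2], [5.6, 4.4, 7.1]
        h, _ = kruskal_wallis([g1, g2])
        assert h == pytest.approx(kruskal_h_oracle(g1, g2))

    def test_matches_scipy_three_groups(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=5) for _ in range(3)]
        h, p = kruskal_wallis(groups)
        h2, p2 = stats.kruskal(*groups)
        assert (h, p) == (pytest.approx(h2), pytest.approx(p2))

    def test_exact_two_group_p(self):
        g1, g2 = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        h, p = kruskal_wallis([g1, g2], exact=True)
        # complete separation: 2 of C(6,3)=20 assignments reach max H
        assert p == pytest.approx(2 / 20)

    def test_null_rejection_small_n_discreteness(self):
        """At n=3 vs 3 the permutation null is discrete (min p = 2/20): the
        exact test rejects below nominal at 0.05, while the chi-square
        approximation is anti-conservative (rejects ~2/20 of the time) --
        the reason the exact option exists."""
        rng = np.random.default_rng(7)
        rej_exact = rej_chi2 = 0
        n_sim = 2000
        for _ in range(n_sim):
            g1, g2 = list(rng.normal(size=3)), list(rng.normal(size=3))
            _, p_chi2 = kruskal_wallis([g1, g2])
            _, p_exact = kruskal_wallis([g1, g2], exact=True)
            rej_chi2 += p_chi2 < 0.05
            rej_exact += p_exact < 0.05
        assert rej_exact / n_sim < 0.05  # discrete null: below nominal
        assert 0.05 < rej_chi2 / n_sim < 0.15  # approximation overshoots


def test_load_ct_table_round_trip(tmp_path):
    df = _ct_table()
    df.loc[0, "ct"] = np.nan
    p = tmp_path / "ct.tsv"
    df.to_csv(p, sep="\t", index=False)
    back = load_ct_table(p)
    assert back.shape == df.shape
    assert back["ct"].isna().sum() == 1
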