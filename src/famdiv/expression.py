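"""Relative qPCR expression via the 2^-ddCt method.

Technical replicates are averaged first; the two (or more) reference genes
are combined as the arithmetic mean of their Ct values, which is geometric
mean normalization in expression space; dCt = Ct_target - mean(Ct_refs);
ddCt subtracts the mean dCt of the calibrator group (the control treatment
at the same tissue/timepoint), so the *geometric* mean of the calibrator
group's fold changes is 1 by construction. The arithmetic mean +- SEM of
the per-biological-replicate 2^-ddCt values is what bar plots display.

Group differences are assessed with the Kruskal-Wallis rank test
(chi-square approximation by default; an exact two-group permutation
option is provided for the tiny sample sizes typical of qPCR designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "FoldChangeResult",
    "load_ct_table",
    "ddct_fold_changes",
    "relative_expression",
    "kruskal_wallis",
]

CT_COLUMNS = ["sample", "gene", "tissue", "timepoint", "treatment",
              "bio_rep", "tech_rep", "ct"]


def load_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV; empty/NA ct fields mean 'undetected'."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct table contains non-positive Ct values")
    return df


@dataclass
class FoldChangeResult:
    """2^-ddCt fold changes for one gene/tissue/timepoint panel."""

    gene: str
    tissue: str
    timepoint: object
    folds: dict[str, np.ndarray]  # treatment -> per-biological-replicate folds
    mean_fold: dict[str, float]
    sem: dict[str, float]
    test_statistic: float | None = None
    p_value: float | None = None
    not_detected: list[str] = field(default_factory=list)  # treatments w/o signal


def _tech_averaged(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates per (gene, treatment, bio_rep)."""
    return (panel.groupby(["gene", "treatment", "bio_rep"], as_index=False)["ct"]
            .mean())


def ddct_fold_changes(ct_table: pd.DataFrame, target_gene: str,
                      reference_genes: list[str], tissue: str, timepoint,
                      calibrator_group: str = "control",
                      exact_test: bool = False) -> FoldChangeResult:
    """Per-replicate 2^-ddCt fold changes for one target in one panel.

    The calibrator is ``calibrator_group`` at the same tissue/timepoint. A
    treatment whose target Ct is undetected in every biological replicate
    is reported under ``not_detected``; an undetected *reference* is an
    error.
    """
    panel = ct_table[(ct_table["tissue"] == tissue)
                     & (ct_table["timepoint"] == timepoint)
                     & (ct_table["gene"].isin([target_gene] + reference_genes))]
    if panel.empty:
        raise ValueError(f"no Ct rows for {target_gene} in {tissue}/{timepoint}")
    avg = _tech_averaged(panel)

    dct: dict[str, dict[int, float]] = {}
    not_detected = []
    for treatment, grp in avg.groupby("treatment"):
        by_gene = {g: sub.set_index("bio_rep")["ct"] for g, sub in grp.groupby("gene")}
        for ref in reference_genes:
            if ref not in by_gene or by_gene[ref].isna().any():
                raise ValueError(
                    f"reference gene {ref!r} undetected in {tissue}/{timepoint}/{treatment}"
                )
        target = by_gene.get(target_gene)
        if target is None or target.isna().all():
            not_detected.append(str(treatment))
            continue
        ref_mean = pd.concat([by_gene[r] for r in reference_genes], axis=1).mean(axis=1)
        vals = (target - ref_mean).dropna()
        dct[str(treatment)] = {int(k): float(v) for k, v in vals.items()}

    if calibrator_group not in dct:
        raise ValueError(
            f"calibrator group {calibrator_group!r} has no detected target "
            f"for {target_gene} in {tissue}/{timepoint}"
        )
    calib_mean = float(np.mean(list(dct[calibrator_group].values())))

    folds = {t: np.array([2.0 ** -(v - calib_mean) for v in sorted_vals(reps)])
             for t, reps in dct.items()}
    mean_fold = {t: float(np.mean(f)) for t, f in folds.items()}
    sem = {t: float(stats.sem(f)) if len(f) > 1 else 0.0 for t, f in folds.items()}

    h = p = None
    if len(folds) >= 2:
        h, p = kruskal_wallis(list(folds.values()), exact=exact_test)
    return FoldChangeResult(target_gene, tissue, timepoint, folds, mean_fold,
                            sem, h, p, not_detected)


def sorted_vals(reps: dict[int, float]) -> list[float]:
    return [reps[k] for k in sorted(reps)]


def relative_expression(ct_table: pd.DataFrame, target_genes: list[str],
                        reference_genes: list[str],
                        calibrator_group: str = "control",
                        exact_test: bool = False) -> list[FoldChangeResult]:
    """Fold changes for every target across all tissue/timepoint panels."""
    results = []
    panels = ct_table[["tissue", "timepoint"]].drop_duplicates().itertuples(index=False)
    for tissue, timepoint in panels:
        for gene in target_genes:
            try:
                res = ddct_fold_changes(ct_table, gene, reference_genes,
                                        tissue, timepoint,
                                        calibrator_group, exact_test)
            except ValueError:
                # target fully absent from the calibrator: report the panel
                # as not detected rather than failing the whole run
                res = FoldChangeResult(gene, tissue, timepoint, {}, {}, {},
                                       not_detected=["all"])
            results.append(res)
    return results


def results_to_rows(results: list[FoldChangeResult]) -> list[dict]:
    rows = []
    for r in results:
        treatments = sorted(set(list(r.folds) + r.not_detected))
        for t in treatments:
            detected = t in r.folds and t != "all"
            rows.append({
                "gene": r.gene, "tissue": r.tissue, "timepoint": r.timepoint,
                "treatment": t,
                "mean_fold": round(r.mean_fold[t], 6) if detected else "not_detected",
                "sem": round(r.sem[t], 6) if detected else ".",
                "n_reps": len(r.folds[t]) if detected else 0,
                "kruskal_H": round(r.test_statistic, 6) if r.test_statistic is not None else ".",
                "p_value": round(r.p_value, 6) if r.p_value is not None else ".",
            })
        if not treatments:
            rows.append({"gene": r.gene, "tissue": r.tissue, "timepoint": r.timepoint,
                         "treatment": "all", "mean_fold": "not_detected", "sem": ".",
                         "n_reps": 0, "kruskal_H": ".", "p_value": "."})
    return rows


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H (used by the exact permutation path)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups: list, exact: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value across >= 2 groups.

    Default p comes from the chi-square approximation with (#groups - 1)
    degrees of freedom; ``exact=True`` enumerates the permutation null
    (two groups, total n <= 12). All-identical data give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if not exact:
        h, p = stats.kruskal(*groups)
        return float(h), float(p)
    if len(groups) != 2:
        raise ValueError("exact Kruskal-Wallis implemented for 2 groups only")
    n1 = len(groups[0])
    n = len(pooled)
    if n > 12:
        raise ValueError("exact Kruskal-Wallis limited to total n <= 12")
    h_obs = _h_statistic(groups)
    count = total = 0
    idx_all = set(range(n))
    for subset in combinations(range(n), n1):
        g1 = pooled[list(subset)]
        g2 = pooled[list(idx_all - set(subset))]
        if _h_statistic([g1, g2]) >= h_obs - 1e-12:
            count += 1
        total += 1
    return float(h_obs), count / total
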