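"""Mutation-sensitivity association testing on screen AUC values.

For every gene carrying non-silent mutations in at least four cell lines,
AUC values of mutant and wild-type lines are compared with a two-sample
t-test (Welch by default, since group variances are rarely equal; the
pooled-variance test is available by flag).  Three cohorts are tested: the
full panel, the panel excluding KRAS-mutant lines, and the panel excluding
lines with either KRAS or NRAS mutations — isolating associations that are
not merely proxies for RAS-pathway genotype.

No multiple-testing correction is applied to the reported p values; a
Benjamini-Hochberg column (``q_bh``) is emitted per cohort for convenience.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["associate_mutations", "COHORTS"]

COHORTS = ("all", "excl_KRAS", "excl_KRAS_NRAS")
MIN_MUTANT = 4
MIN_WILDTYPE = 2


def _cohort_mask(mutations: pd.DataFrame, cohort: str) -> pd.Series:
    mask = pd.Series(True, index=mutations.index)
    if cohort == "all":
        return mask
    drop_genes = {"excl_KRAS": ["KRAS"],
                  "excl_KRAS_NRAS": ["KRAS", "NRAS"]}[cohort]
    for gene in drop_genes:
        if gene in mutations.columns:
            mask &= ~mutations[gene].astype(bool)
    return mask


def _ttest(mut: np.ndarray, wt: np.ndarray, equal_var: bool):
    # Degenerate constant groups: a conventional t-test is undefined; treat
    # equal constants as no evidence (t=0, p=1) and unequal as certainty.
    if mut.std(ddof=1) == 0 and wt.std(ddof=1) == 0:
        if mut.mean() == wt.mean():
            return 0.0, 1.0
        return np.inf if mut.mean() > wt.mean() else -np.inf, 0.0
    res = stats.ttest_ind(mut, wt, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def associate_mutations(auc: pd.Series, mutations: pd.DataFrame,
                        cohorts: Sequence[str] = COHORTS,
                        min_mutant: int = MIN_MUTANT,
                        min_wildtype: int = MIN_WILDTYPE,
                        equal_var: bool = False) -> pd.DataFrame:
    """Per-gene mutant-vs-wild-type AUC comparison across cohorts.

    ``auc`` is indexed by cell line; ``mutations`` is a boolean cell_line x
    gene matrix.  Genes with fewer than ``min_mutant`` mutant or
    ``min_wildtype`` wild-type lines in a cohort are skipped.  The effect
    is mean(AUC_mut) - mean(AUC_wt); negative values mean mutants are more
    sensitive.  Raises on a cell-line key mismatch.
    """
    if not auc.index.isin(mutations.index).all():
        missing = auc.index.difference(mutations.index).tolist()
        raise ValueError(f"cell lines missing from mutation matrix: {missing}")
    mutations = mutations.loc[auc.index].astype(bool)

    rows = []
    for cohort in cohorts:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort rule {cohort!r}")
        mask = _cohort_mask(mutations, cohort)
        sub_auc = auc[mask]
        sub_mut = mutations.loc[mask]
        for gene in sub_mut.columns:
            is_mut = sub_mut[gene].to_numpy()
            mut_vals = sub_auc.to_numpy()[is_mut]
            wt_vals = sub_auc.to_numpy()[~is_mut]
            if mut_vals.size < min_mutant or wt_vals.size < min_wildtype:
                continue
            t, p = _ttest(mut_vals, wt_vals, equal_var)
            rows.append((gene, cohort, mut_vals.size, wt_vals.size,
                         float(mut_vals.mean() - wt_vals.mean()), t, p))
    out = pd.DataFrame(rows, columns=["gene", "cohort", "n_mut", "n_wt",
                                      "effect", "t", "p"])
    if not out.empty:
        out["q_bh"] = np.nan
        for cohort in out["cohort"].unique():
            ix = out["cohort"] == cohort
            out.loc[ix, "q_bh"] = multipletests(out.loc[ix, "p"],
                                                method="fdr_bh")[1]
    return out
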