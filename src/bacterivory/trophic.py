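"""Trophic-mode comparison of relative gene expression and marker selection.

For each gene, species, and sample, the observation is the gene's share of
that species' total expression (CPM of the gene's CDS divided by the
species' total CPM in the sample). Heterotroph and phototroph observations
are compared with a one-sided randomization test (difference of group
means, labels shuffled over the pooled observations); genes testable only
in heterotrophs can instead qualify through an observation-imbalance rule.
The final bacterivory markers are the genes that are both more expressed
in heterotrophs and flagged by the community fold-change analysis.

The permutation p-value uses the add-one estimator
p = (1 + #{perm >= observed}) / (n_perm + 1), which never returns zero. No
multiple-testing correction is applied; results are reported gene by gene
at the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

DECISION_MORE_HET = "more_in_heterotrophs"
DECISION_NOT_SIG = "not_significant"
DECISION_SKIPPED = "skipped_low_n"
DECISION_IMBALANCE = "imbalance_rule"


def relative_expression(
    cpm_long: pd.DataFrame,
    totals: pd.DataFrame,
    gene_map: pd.DataFrame,
    trophic_labels: pd.DataFrame,
) -> pd.DataFrame:
    """Per (gene, species, sample) relative expression observations.

    ``cpm_long`` has columns (species, cds_id, sample, cpm); ``gene_map``
    maps cds_id -> gene (columns cds_id, gene; CDS absent from the map carry
    no gene and yield no observation — absence is not a zero); ``totals`` is
    the species x sample total-CPM table; ``trophic_labels`` has columns
    (species, trophic_mode). Species/sample pairs with zero total are
    dropped with a warning.

    Returns (gene_id, species_id, sample_id, trophic_mode, rel_expr).
    """
    mode = dict(zip(trophic_labels["species"], trophic_labels["trophic_mode"]))
    gmap = dict(zip(gene_map["cds_id"], gene_map["gene"]))
    df = cpm_long.copy()
    df["gene_id"] = df["cds_id"].map(gmap)
    df = df[df["gene_id"].notna()]
    # gene CPM per (gene, species, sample): sum over the gene's CDS
    obs = (df.groupby(["gene_id", "species", "sample"], sort=True)["cpm"]
           .sum().reset_index())
    tot = totals.stack()
    denom = obs.apply(lambda r: tot.get((r["species"], r["sample"]), 0.0), axis=1)
    zero = denom <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} species/sample pairs with zero total dropped")
        obs, denom = obs[~zero], denom[~zero]
    out = pd.DataFrame({
        "gene_id": obs["gene_id"].to_numpy(),
        "species_id": obs["species"].to_numpy(),
        "sample_id": obs["sample"].to_numpy(),
        "trophic_mode": obs["species"].map(mode).to_numpy(),
        "rel_expr": (obs["cpm"] / denom).to_numpy(),
    })
    if out["trophic_mode"].isna().any():
        raise InputError("species without trophic-mode label in the observations")
    return out


def imbalance_rule(n_het: int, n_pho: int, min_n: int = 15,
                   ratio_threshold: float = 5.0) -> bool:
    """Qualify a gene untestable in phototrophs: true iff the heterotroph
    group is large enough on its own (>= min_n) and outnumbers phototroph
    observations by at least ``ratio_threshold`` to one."""
    return n_het >= min_n and n_het >= ratio_threshold * max(n_pho, 1)


@dataclass
class TrophicTestResult:
    gene_id: str
    n_het: int
    n_pho: int
    observed_stat: float
    p_value: float
    decision: str


def randomization_test(
    het: np.ndarray,
    pho: np.ndarray,
    n_perm: int = 10000,
    min_n: int = 15,
    alpha: float = 0.05,
    imbalance_ratio: float = 5.0,
    rng: np.random.Generator | None = None,
    gene_id: str = "",
    statistic: str = "mean",
) -> TrophicTestResult:
    """One-sided permutation test of heterotroph > phototroph relative expression.

    The statistic is mean(het) - mean(pho) (or medians with
    ``statistic='median'``); the null is built by shuffling trophic labels
    over the pooled observations ``n_perm`` times, and
    p = (1 + #{perm stat >= observed}) / (n_perm + 1). The test runs only
    when both groups have at least ``min_n`` observations; otherwise the
    gene is skipped unless the imbalance rule qualifies it.
    """
    if rng is None:
        rng = np.random.default_rng()
    het = np.asarray(het, dtype=float)
    pho = np.asarray(pho, dtype=float)
    n_het, n_pho = len(het), len(pho)

    if min(n_het, n_pho) < min_n:
        decision = DECISION_IMBALANCE if imbalance_rule(
            n_het, n_pho, min_n, imbalance_ratio) else DECISION_SKIPPED
        stat = float(het.mean() - pho.mean()) if n_het and n_pho else np.nan
        return TrophicTestResult(gene_id, n_het, n_pho, stat, np.nan, decision)

    agg = np.median if statistic == "median" else np.mean
    observed = float(agg(het) - agg(pho))
    pooled = np.concatenate([het, pho])
    if np.ptp(pooled) == 0:
        return TrophicTestResult(gene_id, n_het, n_pho, observed, 1.0, DECISION_NOT_SIG)

    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, len(pooled))).copy(), axis=1)
    if statistic == "median":
        stats = (np.median(perms[:, :n_het], axis=1)
                 - np.median(perms[:, n_het:], axis=1))
    else:
        stats = perms[:, :n_het].mean(axis=1) - perms[:, n_het:].mean(axis=1)
    # tolerance so permutations tied with the observed statistic count as >=
    # despite summation-order rounding
    eps = 1e-12 * max(1.0, float(np.max(np.abs(pooled))))
    p = (1.0 + float(np.sum(stats >= observed - eps))) / (n_perm + 1.0)
    decision = DECISION_MORE_HET if p < alpha else DECISION_NOT_SIG
    return TrophicTestResult(gene_id, n_het, n_pho, observed, p, decision)


def test_all_genes(
    observations: pd.DataFrame,
    n_perm: int = 10000,
    min_n: int = 15,
    alpha: float = 0.05,
    imbalance_ratio: float = 5.0,
    seed: int = 0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Run the randomization test for every gene in an observations table.

    Mixotroph observations are carried through the table but excluded from
    the two-group comparison. Returns one row per gene with columns
    (gene_id, n_het, n_pho, observed_stat, p_value, decision).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    rows = []
    for gene, grp in observations.groupby("gene_id", sort=True):
        het = grp.loc[grp["trophic_mode"] == "heterotroph", "rel_expr"].to_numpy()
        pho = grp.loc[grp["trophic_mode"] == "phototroph", "rel_expr"].to_numpy()
        res = randomization_test(het, pho, n_perm=n_perm, min_n=min_n, alpha=alpha,
                                 imbalance_ratio=imbalance_ratio, rng=rng,
                                 gene_id=gene, statistic=statistic)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def select_markers(
    test_results: pd.DataFrame,
    fc_flags: set[str],
    require_same_universe: bool = False,
) -> pd.DataFrame:
    """Combine the trophic test with the fold-change flags.

    A gene is a final marker iff its decision is ``more_in_heterotrophs`` or
    ``imbalance_rule`` AND it was fold-change flagged (over the housekeeping
    baseline in enough incubations). With ``require_same_universe`` the
    fold-change flags must refer only to tested genes.

    Returns the results table with ``fc_flag``/``final_marker`` columns,
    sorted by p-value then by mean heterotroph relative expression (markers
    first).
    """
    out = test_results.copy()
    if require_same_universe:
        extra = sorted(set(fc_flags) - set(out["gene_id"]))
        if extra:
            raise InputError(f"fold-change flags outside the tested gene universe: {extra}")
    out["fc_flag"] = out["gene_id"].isin(fc_flags)
    out["final_marker"] = out["decision"].isin([DECISION_MORE_HET, DECISION_IMBALANCE]) \
        & out["fc_flag"]
    out = out.sort_values(["final_marker", "p_value", "observed_stat"],
                          ascending=[False, True, False], kind="mergesort")
    return out.reset_index(drop=True)
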