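"""Independent brute-force oracles used only by the test suite.

These re-derive the quantities the package computes, with explicit loops
and no shared code paths, so agreement is evidence of correctness rather
than of self-consistency.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tmm_oracle(counts: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values factors, computed with explicit loops.

    counts: genes x samples integer array. Returns one factor per sample,
    geometric mean 1.
    """
    n_genes, n_samples = counts.shape
    lib = [sum(counts[g][s] for g in range(n_genes)) for s in range(n_samples)]

    # reference: 75th percentile of library-scaled counts closest to the mean
    def quantile75(values):
        v = sorted(values)
        h = (len(v) - 1) * 0.75  # linear interpolation, like numpy default
        lo = math.floor(h)
        hi = math.ceil(h)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    f75 = [quantile75([counts[g][s] / lib[s] for g in range(n_genes)])
           for s in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - mean75))

    def avg_rank(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    factors = []
    for s in range(n_samples):
        if s == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, ws = [], [], []
        for g in range(n_genes):
            o, r = counts[g][s], counts[g][ref]
            if o > 0 and r > 0:
                po, pr = o / lib[s], r / lib[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * math.log2(po * pr))
                ws.append((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not m_vals:
            factors.append(1.0)
            continue
        if max(abs(m) for m in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        rm, ra = avg_rank(m_vals), avg_rank(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += m_vals[i] / ws[i]
                den += 1.0 / ws[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)

    log_mean = sum(math.log(f) for f in factors) / n_samples
    return np.array([f / math.exp(log_mean) for f in factors])


def exact_permutation_pvalue(het, pho) -> float:
    """One-sided p-value of mean(het) - mean(pho) by exhaustive enumeration
    over all assignments of which pooled observations are labeled het."""
    pooled = list(het) + list(pho)
    n_het = len(het)
    observed = sum(het) / n_het - sum(pho) / len(pho)
    n_pho = len(pho)
    total = 0
    ge = 0
    for idx in itertools.combinations(range(len(pooled)), n_het):
        chosen = set(idx)
        h = [pooled[i] for i in chosen]
        p = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        stat = sum(h) / n_het - sum(p) / n_pho
        total += 1
        if stat >= observed - 1e-12:
            ge += 1
    return ge / total


def top_hit_oracle(hits: list[dict], min_pident: float = 90.0, min_aln: int = 50) -> dict:
    """Exhaustive-comparison assignment of transcripts to species.

    hits: list of dicts with keys qseqid, species_id, pident, length,
    bitscore, evalue. Filters are applied first; then for every transcript
    the set of hits sharing the best rounded bitscore (or the best hit's
    exact e-value within bitscore rounding) is inspected: one species wins,
    several species discard the transcript.
    """
    kept = [h for h in hits if h["pident"] > min_pident and h["length"] >= min_aln]
    by_q: dict[str, list[dict]] = {}
    for h in kept:
        by_q.setdefault(h["qseqid"], []).append(h)
    out = {}
    for q, rows in by_q.items():
        best = max(rows, key=lambda h: h["bitscore"])
        tied_species = set()
        for h in rows:
            same_bits = round(h["bitscore"], 2) == round(best["bitscore"], 2)
            same_ev = (h["evalue"] == best["evalue"]
                       and abs(h["bitscore"] - best["bitscore"]) <= 0.01)
            if same_bits or same_ev:
                tied_species.add(h["species_id"])
        if len(tied_species) == 1:
            out[q] = next(iter(tied_species))
    return out
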