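"""Synthetic incubation data with planted ground truth.

Generates the four input surfaces the downstream pipeline consumes —
microscopy growth curves, an annotated transcript x sample TPM table,
protein/nucleotide alignment tables, and per-species CDS read counts —
with known planted effects (marker up-regulation during heterotrophic
flagellate growth, housekeeping stability, reference species at chosen
nucleotide divergence, trophic-mode expression shifts) so every stage of
the analysis can be exercised and scored with no external data.

All randomness flows from one integer seed through independent
sub-streams (one per generator), so each table can be regenerated on its
own and identical (config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, TROPHIC_MODES
from .errors import ConfigError, InputError
from .states import classify_states

POPULATIONS = ("bacteria", "hf", "pf", "synechococcus")
TAXA = ("MAST-4", "MAST-7", "MAST-1", "Chrysophyceae", "Telonemia",
        "Prymnesiophyceae", "Chlorophyta", "unclassified")

# shape constants of the deterministic growth templates (1/day)
_BACT_DECLINE = 0.25
_HF_DECLINE = 0.35
_LOGISTIC_SATURATION = 0.99  # template reaches this fraction of the peak at peak day

_STREAM_GROWTH, _STREAM_TRANSCRIPTS, _STREAM_ALIGN, _STREAM_COUNTS = range(4)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated experiment."""

    marker_ko_ids: set[str] = field(default_factory=set)
    hk_ko_ids: set[str] = field(default_factory=set)
    photo_ko_ids: set[str] = field(default_factory=set)
    state_of_sample: dict[str, str] = field(default_factory=dict)
    species_status: dict[str, str] = field(default_factory=dict)   # present|relative|absent
    trophic_mode: dict[str, str] = field(default_factory=dict)
    species_marker_genes: list[str] = field(default_factory=list)
    genes_absent_in_phototrophs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("marker_ko_ids", "hk_ko_ids", "photo_ko_ids"):
            d[key] = sorted(d[key])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("marker_ko_ids", "hk_ko_ids", "photo_ko_ids"):
            d[key] = set(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def _growth_template(times: np.ndarray, n0: float, peak: float, t_lag: float,
                     t_peak: float, decline_rate: float) -> np.ndarray:
    """Lag -> logistic rise reaching `peak` at t_peak -> exponential decline."""
    q = _LOGISTIC_SATURATION
    carrying = peak / q
    # rate such that the logistic started at t_lag hits q * carrying at t_peak
    r = (np.log((carrying - n0) / n0) - np.log((1 - q) / q)) / (t_peak - t_lag)
    out = np.empty_like(times, dtype=float)
    for i, t in enumerate(times):
        if t <= t_lag:
            out[i] = n0
        elif t <= t_peak:
            out[i] = carrying / (1.0 + ((carrying - n0) / n0) * np.exp(-r * (t - t_lag)))
        else:
            out[i] = peak * np.exp(-decline_rate * (t - t_peak))
    return out


def simulate_growth_curves(
    config: SimulationConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate microscopy count series and pick metatranscriptome sampling times.

    Returns
    -------
    curves : DataFrame with columns (incubation, time_days, population, cells_per_ml),
        counts carrying multiplicative lognormal noise of CV
        ``config.count_noise_cv`` (microscopy counting error).
    samples : DataFrame with columns (sample_id, incubation, time_days, state),
        where ``state`` is the planted truth label obtained by applying the
        growth-state rule to the *noiseless* HF template.
    """
    rng = _rng(seed, _STREAM_GROWTH)
    times = np.round(np.arange(0.0, config.duration + 1e-9, config.count_interval), 6)
    curve_rows = []
    sample_rows = []
    lo_s, hi_s = config.samples_per_incubation
    for i in range(1, config.n_incubations + 1):
        inc = f"inc{i}"
        b0 = rng.uniform(*config.bacteria_init)
        bpk = rng.uniform(*config.bacteria_peak)
        bday = rng.uniform(*config.bacteria_peak_day)
        h0 = rng.uniform(*config.hf_init)
        hpk = rng.uniform(*config.hf_peak)
        hday = rng.uniform(*config.hf_peak_day)
        hlag = rng.uniform(*config.hf_lag_days)
        if hday >= config.duration or bday >= hday:
            raise ConfigError("duration too short to place the bacterial peak before the HF peak")
        pf0 = rng.uniform(*config.pf_init)
        syn0 = rng.uniform(*config.syn_init)

        templates = {
            "bacteria": _growth_template(times, b0, bpk, 0.3, bday, _BACT_DECLINE),
            "hf": _growth_template(times, h0, hpk, hlag, hday, _HF_DECLINE),
            "pf": pf0 * np.exp(-config.decay_rate * times),
            "synechococcus": syn0 * np.exp(-config.decay_rate * times),
        }
        for pop in POPULATIONS:
            noisy = templates[pop] * _lognormal_noise(rng, config.count_noise_cv, len(times))
            for t, c in zip(times, noisy):
                curve_rows.append((inc, float(t), pop, float(c)))

        # metatranscriptome sampling times, evenly spread over the incubation
        n_s = int(rng.integers(lo_s, hi_s + 1))
        sample_times = np.round(np.linspace(0.5, config.duration - 0.5, n_s), 3)
        clean = pd.DataFrame(
            {"incubation": inc, "time_days": times, "population": "hf",
             "cells_per_ml": templates["hf"]}
        )
        truth_states = classify_states(clean, list(sample_times))
        for j, (t, st) in enumerate(zip(sample_times, truth_states["state"]), start=1):
            sample_rows.append((f"{inc}_s{j}", inc, float(t), st))

    curves = pd.DataFrame(curve_rows, columns=["incubation", "time_days", "population", "cells_per_ml"])
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "incubation", "time_days", "state"])
    return curves, samples


# ---------------------------------------------------------------------------
# community transcript table
# ---------------------------------------------------------------------------

def simulate_transcript_table(
    config: SimulationConfig,
    samples: pd.DataFrame,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the transcript x sample TPM table with planted KO effects.

    Marker KOs are up-regulated by ``marker_fold_change`` in growth (and stay
    elevated in decline), housekeeping KOs are flat, photosynthesis KOs decay
    to near zero by the decline state, and the remaining background is scaled
    per state so that expected column totals are equal — the planted ratios
    therefore survive the per-sample TPM normalization in expectation.
    Each per-sample TPM column sums to 10^6.
    """
    if truth is None:
        truth = SyntheticTruth()
    required = {"sample_id", "state"}
    if not required.issubset(samples.columns):
        raise InputError("samples table must provide sample_id and state columns")
    if samples["state"].isna().any():
        raise InputError("states must cover all samples")
    if config.n_marker_kos + config.n_hk_kos + config.n_photo_kos > config.n_kos:
        raise ConfigError("planted KO sets exceed the KO pool")

    rng = _rng(seed, _STREAM_TRANSCRIPTS)
    kos = np.array([f"K{i + 1:05d}" for i in range(config.n_kos)])
    rng.shuffle(kos)
    markers = kos[: config.n_marker_kos]
    hk = kos[config.n_marker_kos: config.n_marker_kos + config.n_hk_kos]
    photo = kos[config.n_marker_kos + config.n_hk_kos:
                config.n_marker_kos + config.n_hk_kos + config.n_photo_kos]
    background_kos = kos[config.n_marker_kos + config.n_hk_kos + config.n_photo_kos:]
    truth.marker_ko_ids = set(markers)
    truth.hk_ko_ids = set(hk)
    truth.photo_ko_ids = set(photo)

    n_annot = int(round(config.n_transcripts * config.ko_annotation_fraction))
    if n_annot < 2 * config.n_kos:
        raise ConfigError("too few annotated transcripts to give every KO >= 2 transcripts")

    # each KO gets two guaranteed transcripts; the rest follow a lognormal popularity
    ko1 = np.concatenate([np.repeat(kos, 2), np.empty(0, dtype=kos.dtype)])
    popularity = rng.lognormal(0.0, 1.0, size=config.n_kos)
    extra = rng.choice(kos, size=n_annot - 2 * config.n_kos, p=popularity / popularity.sum())
    ko1 = np.concatenate([ko1, extra])
    rng.shuffle(ko1)

    # plant KO-pair overlap structure among background KOs only
    n_pairable = (len(background_kos) // 2) * 2
    partner: dict[str, str] = {}
    for a, b in zip(background_kos[:n_pairable:2], background_kos[1:n_pairable:2]):
        partner[a] = b
        partner[b] = a
    pairable_idx = np.flatnonzero(np.isin(ko1, list(partner)))
    n_two = min(int(round(config.two_ko_fraction * n_annot)), len(pairable_idx))
    two_idx = rng.choice(pairable_idx, size=n_two, replace=False) if n_two else np.empty(0, int)

    ko_ids = np.array([""] * config.n_transcripts, dtype=object)
    annot_slots = rng.choice(config.n_transcripts, size=n_annot, replace=False)
    for slot, ko in zip(annot_slots, ko1):
        ko_ids[slot] = ko
    for j in two_idx:
        slot = annot_slots[j]
        ko_ids[slot] = ko_ids[slot] + ";" + partner[ko1[j]]

    taxon = rng.choice(TAXA, size=config.n_transcripts,
                       p=[0.18, 0.15, 0.1, 0.12, 0.1, 0.08, 0.07, 0.2])
    base = rng.lognormal(0.0, 1.6, size=config.n_transcripts)

    primary_ko = np.array([k.split(";")[0] if k else "" for k in ko_ids])
    is_marker = np.isin(primary_ko, markers)
    is_photo = np.isin(primary_ko, photo)
    is_hk = np.isin(primary_ko, hk)
    is_bg = ~(is_marker | is_photo | is_hk)
    # markers emulate the highly expressed bacterivory genes: boost their
    # baseline so they sit in the upper expression tier even in the lag state
    base[is_marker] *= config.marker_expression_boost

    fc = config.marker_fold_change
    marker_mult = {"lag": 1.0, "growth": fc, "decline": fc}
    photo_mult = {"lag": 1.0, "growth": 0.15, "decline": 0.02}

    s_tot = base.sum()
    s_mk, s_ph, s_hk_w = base[is_marker].sum(), base[is_photo].sum(), base[is_hk].sum()
    s_bg = base[is_bg].sum()

    data = {}
    for sample_id, state in zip(samples["sample_id"], samples["state"]):
        mult = np.ones(config.n_transcripts)
        mult[is_marker] = marker_mult[state]
        mult[is_photo] = photo_mult[state]
        # rescale background so the expected column total is state-independent
        bg_scale = (s_tot - s_hk_w - marker_mult[state] * s_mk - photo_mult[state] * s_ph) / s_bg
        if bg_scale <= 0:
            raise ConfigError("planted effects leave no room for background expression")
        mult[is_bg] = bg_scale
        raw = base * mult * _lognormal_noise(rng, config.noise_cv, config.n_transcripts)
        data[sample_id] = raw / raw.sum() * 1e6

    table = pd.DataFrame(
        {"transcript_id": [f"T{i + 1:06d}" for i in range(config.n_transcripts)],
         "ko_ids": ko_ids, "taxon": taxon, **data}
    )
    truth.state_of_sample = dict(zip(samples["sample_id"], samples["state"]))
    return table, truth


# ---------------------------------------------------------------------------
# alignment tables
# ---------------------------------------------------------------------------

def _assign_by_proportions(items: list[str], proportions, labels,
                           rng: np.random.Generator) -> dict[str, str]:
    """Largest-remainder allocation of labels to items, order randomized."""
    n = len(items)
    counts = [int(np.floor(p * n)) for p in proportions]
    remainders = [p * n - c for p, c in zip(proportions, counts)]
    while sum(counts) < n:
        k = int(np.argmax(remainders))
        counts[k] += 1
        remainders[k] = -1
    pool = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    order = rng.permutation(n)
    return {items[i]: pool[j] for j, i in enumerate(order)}


def simulate_alignments(
    config: SimulationConfig,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    incubations: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate protein and nucleotide alignment tables (BLAST outfmt-6 layout).

    Species planted "present" carry low nucleotide divergence (median identity
    well above 99%); "relative" species sit in the 90-95% identity band that
    must be rejected downstream; "absent" species emit no hits. A configurable
    fraction of transcripts receives a second, equal-score top hit to a
    different species (the tie fixture), and sub-threshold decoy alignments
    exercise the identity/length filters.

    Returns (protein_hits, nucleotide_hits, species_map, truth).
    """
    if not config.species_identity_profile:
        raise ConfigError("species_identity_profile must be non-empty")
    if truth is None:
        truth = SyntheticTruth()
    rng = _rng(seed, _STREAM_ALIGN)
    if incubations is None:
        incubations = [f"inc{i}" for i in range(1, config.n_incubations + 1)]

    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    # status allocation from the identity profile; remainder is absent
    statuses: list[tuple[str, float]] = []
    for frac, div in config.species_identity_profile:
        label = "present" if (100.0 - div) > 99.3 else "relative"
        statuses.append((label, div))
    fracs = [f for f, _ in config.species_identity_profile]
    fracs.append(max(0.0, 1.0 - sum(fracs)))
    labels = list(range(len(statuses))) + [-1]  # -1 = absent
    assignment = _assign_by_proportions(species, fracs, labels, rng)
    divergence: dict[str, float] = {}
    for sp in species:
        k = assignment[sp]
        if k == -1:
            truth.species_status[sp] = "absent"
        else:
            truth.species_status[sp] = statuses[k][0]
            divergence[sp] = statuses[k][1]

    # trophic modes, allocated within each status group so that present
    # species always include both heterotrophs and phototrophs
    for status in ("present", "relative", "absent"):
        group = [sp for sp in species if truth.species_status[sp] == status]
        if group:
            truth.trophic_mode.update(_assign_by_proportions(
                group, config.trophic_mode_proportions, TROPHIC_MODES, rng))

    prot_rows: list[pd.DataFrame] = []
    nt_rows: list[pd.DataFrame] = []
    map_rows: list[tuple[str, str]] = []
    active = [sp for sp in species if truth.species_status[sp] != "absent"]
    other_species = {sp: [s for s in active if s != sp] for sp in active}

    for sp in active:
        div = divergence[sp]
        home_inc = int(rng.integers(len(incubations)))
        for k, inc in enumerate(incubations):
            if k == home_inc:
                n_tr = int(rng.integers(config.min_present_transcripts,
                                        int(config.min_present_transcripts * 2.5)))
            else:
                n_tr = int(rng.integers(20, config.min_present_transcripts))
            qid = np.array([f"{inc}_tq_{sp}_{j:05d}" for j in range(n_tr)])

            # --- protein hits (identity on the amino-acid scale) -----------
            prot_pident = np.clip(rng.normal(100.0 - 0.7 * div, 0.8, n_tr), 90.3, 100.0)
            aln = rng.integers(60, 400, n_tr)
            bits = np.round(2.0 * aln * prot_pident / 100.0, 1)
            evalue = _evalue(bits)
            sid = np.array([f"{sp}_p{int(j)}" for j in rng.integers(0, config.n_cds_per_species, n_tr)])
            prot_rows.append(_outfmt6(qid, sid, prot_pident, aln, evalue, bits))

            # sub-threshold decoys: too short, or identity below the 90% gate
            n_junk = n_tr // 10
            if n_junk:
                pick = rng.choice(n_tr, n_junk, replace=False)
                short = rng.integers(20, 50, n_junk)
                junk_bits = np.round(2.2 * short * 0.99, 1)  # high per-residue score, short
                prot_rows.append(_outfmt6(
                    qid[pick], np.array([f"{sp}_p{0}"] * n_junk),
                    np.clip(rng.normal(96, 2, n_junk), 91, 100), short,
                    _evalue(junk_bits), junk_bits))
                low_id = np.clip(rng.normal(80, 5, n_junk), 40, 89.9)
                prot_rows.append(_outfmt6(
                    qid[pick], np.array([f"{sp}_p{1}"] * n_junk),
                    low_id, rng.integers(60, 400, n_junk), evalue[pick], bits[pick] + 5.0))

            # weaker cross-species hits
            if other_species[sp]:
                n_x = n_tr // 2
                pick = rng.choice(n_tr, n_x, replace=False)
                xsp = rng.choice(other_species[sp], n_x)
                xbits = np.round(bits[pick] * rng.uniform(0.5, 0.9, n_x), 1)
                xsid = np.array([f"{s}_p{int(j)}" for s, j in
                                 zip(xsp, rng.integers(0, config.n_cds_per_species, n_x))])
                prot_rows.append(_outfmt6(
                    qid[pick], xsid, np.clip(rng.normal(92.5, 1.5, n_x), 90.2, 96.0),
                    aln[pick], _evalue(xbits), xbits))

                # equal-score ties to a different species
                n_tie = rng.binomial(n_tr, config.tie_fraction)
                if n_tie:
                    pick = rng.choice(n_tr, n_tie, replace=False)
                    tsp = rng.choice(other_species[sp], n_tie)
                    tsid = np.array([f"{s}_p{int(j)}" for s, j in
                                     zip(tsp, rng.integers(0, config.n_cds_per_species, n_tie))])
                    prot_rows.append(_outfmt6(
                        qid[pick], tsid, prot_pident[pick], aln[pick], evalue[pick], bits[pick]))

            # --- nucleotide hits vs the species' own CDS --------------------
            if truth.species_status[sp] == "present":
                nt_pident = np.clip(rng.normal(100.0 - div, 0.3, n_tr), 98.8, 100.0)
            else:
                nt_pident = np.clip(rng.normal(100.0 - div, 1.2, n_tr), 90.0, 95.0)
            nt_len = rng.integers(200, 1500, n_tr)
            nt_bits = np.round(1.9 * nt_len * nt_pident / 100.0, 1)
            nt_sid = np.array([f"{sp}_cds{int(j)}"
                               for j in rng.integers(0, config.n_cds_per_species, n_tr)])
            nt_rows.append(_outfmt6(qid, nt_sid, nt_pident, nt_len,
                                    _evalue(nt_bits), nt_bits))

    for sp in active:
        for j in range(config.n_cds_per_species):
            map_rows.append((f"{sp}_p{j}", sp))
            map_rows.append((f"{sp}_cds{j}", sp))

    prot = pd.concat(prot_rows, ignore_index=True) if prot_rows else _outfmt6_empty()
    nt = pd.concat(nt_rows, ignore_index=True) if nt_rows else _outfmt6_empty()
    species_map = pd.DataFrame(map_rows, columns=["subject_id", "species_id"])
    return prot, nt, species_map, truth


def _evalue(bits) -> np.ndarray:
    """Map bitscores to e-values monotonically; equal bitscores share an
    e-value, distinct ones never collide (no saturation at the small end)."""
    return 10.0 ** (-np.asarray(bits, dtype=float) / 10.0)


def _outfmt6(qid, sid, pident, length, evalue, bits) -> pd.DataFrame:
    length = np.asarray(length)
    pident = np.round(np.asarray(pident, dtype=float), 1)
    mismatch = np.round(length * (1.0 - pident / 100.0)).astype(int)
    return pd.DataFrame({
        "qseqid": qid, "sseqid": sid, "pident": pident, "length": length,
        "mismatch": mismatch, "gapopen": 0, "qstart": 1, "qend": length,
        "sstart": 1, "send": length, "evalue": evalue, "bitscore": bits,
    })


def _outfmt6_empty() -> pd.DataFrame:
    return _outfmt6(np.array([], dtype=object), np.array([], dtype=object),
                    np.array([]), np.array([], dtype=int), np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# per-species CDS counts
# ---------------------------------------------------------------------------

def simulate_species_counts(
    config: SimulationConfig,
    samples: pd.DataFrame,
    truth: SyntheticTruth,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate CDS-level read counts for the planted-present species.

    Marker genes occupy a share of each species' expression equal to a
    per-gene base share times ``relative_expression_effect`` in heterotrophs
    (sqrt of it in mixotrophs, 1x in phototrophs); per-species shares sum to
    one, so the expected heterotroph/phototroph relative-expression ratio is
    exactly the configured effect. Heterotroph totals rise from lag to
    growth/decline and phototroph totals fall. Effective lengths vary per CDS
    and raw counts scale with them, so length correction is exercised.

    Returns (counts, gene_map, species_metadata, truth) where counts is long
    form (species, cds_id, sample, read_count, effective_length).
    """
    rng = _rng(seed, _STREAM_COUNTS)
    present = sorted(sp for sp, st in truth.species_status.items() if st == "present")
    if not present:
        raise ConfigError("no species planted present; nothing to quantify")
    if not truth.marker_ko_ids:
        raise ConfigError("transcript-table truth (marker KOs) required before species counts")

    genes = sorted(truth.marker_ko_ids)[: config.n_species_marker_genes]
    truth.species_marker_genes = genes
    absent_pho = genes[len(genes) - config.genes_absent_in_phototrophs:] \
        if config.genes_absent_in_phototrophs else []
    truth.genes_absent_in_phototrophs = list(absent_pho)

    base_share = dict(zip(genes, rng.uniform(0.001, 0.004, len(genes))))
    eff = config.relative_expression_effect
    mode_mult = {"heterotroph": eff, "mixotroph": float(np.sqrt(eff)), "phototroph": 1.0}
    depth = {"heterotroph": {"lag": 0.5, "growth": 3.0, "decline": 4.0},
             "phototroph": {"lag": 4.0, "growth": 1.5, "decline": 0.5},
             "mixotroph": {"lag": 2.0, "growth": 2.0, "decline": 2.0}}
    base_depth = 2e5  # reads per species and sample at trend multiplier 1

    count_frames = []
    map_rows = []
    meta_rows = []
    sample_ids = list(samples["sample_id"])
    sample_states = list(samples["state"])
    for sp in present:
        mode = truth.trophic_mode[sp]
        meta_rows.append((sp, mode))
        n_cds = config.n_cds_per_species
        cds_ids = np.array([f"{sp}_cds{j}" for j in range(n_cds)])
        efflen = rng.integers(300, 3001, n_cds).astype(float)

        sp_genes = [g for g in genes if not (mode == "phototroph" and g in absent_pho)]
        share = np.zeros(n_cds)
        gene_of = np.array([""] * n_cds, dtype=object)
        cursor = 0
        for g in sp_genes:
            k = int(rng.integers(1, 4))  # 1-3 CDS per gene
            gshare = base_share[g] * mode_mult[mode]
            split = rng.dirichlet(np.ones(k)) * gshare
            share[cursor:cursor + k] = split
            gene_of[cursor:cursor + k] = g
            cursor += k
        n_bg = n_cds - cursor
        bg_w = rng.lognormal(0.0, 1.0, n_bg)
        share[cursor:] = (1.0 - share.sum()) * bg_w / bg_w.sum()

        order = rng.permutation(n_cds)
        share, gene_of, efflen, cds_ids = share[order], gene_of[order], efflen[order], cds_ids[order]
        for cid, g in zip(cds_ids, gene_of):
            if g:
                map_rows.append((cid, sp, g))

        noise = _lognormal_noise(rng, config.noise_cv, (n_cds, len(sample_ids)))
        totals = np.array([depth[mode][st] * base_depth for st in sample_states])
        expected = share[:, None] * totals[None, :] * (efflen[:, None] / 1000.0)
        counts = np.rint(expected * noise).astype(int)
        frame = pd.DataFrame(counts, columns=sample_ids)
        frame.insert(0, "effective_length", efflen.astype(int))
        frame.insert(0, "cds_id", cds_ids)
        frame.insert(0, "species", sp)
        count_frames.append(frame.melt(
            id_vars=["species", "cds_id", "effective_length"],
            var_name="sample", value_name="read_count"))

    counts = pd.concat(count_frames, ignore_index=True)
    counts = counts[["species", "cds_id", "sample", "read_count", "effective_length"]]
    gene_map = pd.DataFrame(map_rows, columns=["cds_id", "species", "gene"])
    metadata = pd.DataFrame(meta_rows, columns=["species", "trophic_mode"])
    return counts, gene_map, metadata, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    seed: int
    curves: pd.DataFrame
    samples: pd.DataFrame
    transcripts: pd.DataFrame
    protein_hits: pd.DataFrame
    nucleotide_hits: pd.DataFrame
    species_map: pd.DataFrame
    species_counts: pd.DataFrame
    gene_map: pd.DataFrame
    species_metadata: pd.DataFrame
    truth: SyntheticTruth


def simulate_all(config: SimulationConfig, seed: int = 0) -> SimulatedExperiment:
    """Run all four generators off one seed and return the bundled experiment."""
    curves, samples = simulate_growth_curves(config, seed)
    transcripts, truth = simulate_transcript_table(config, samples, seed)
    prot, nt, species_map, truth = simulate_alignments(config, seed, truth)
    counts, gene_map, metadata, truth = simulate_species_counts(config, samples, truth, seed)
    return SimulatedExperiment(config, seed, curves, samples, transcripts,
                               prot, nt, species_map, counts, gene_map, metadata, truth)


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated table as TSV (+ the truth as JSON); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "curves": outdir / "growth_curves.tsv",
        "samples": outdir / "samples.tsv",
        "transcripts": outdir / "transcript_table.tsv",
        "protein_hits": outdir / "protein_hits.tsv",
        "nucleotide_hits": outdir / "nucleotide_hits.tsv",
        "species_map": outdir / "species_map.tsv",
        "species_counts": outdir / "species_counts.tsv",
        "gene_map": outdir / "gene_map.tsv",
        "species_metadata": outdir / "species_metadata.tsv",
        "truth": outdir / "truth.json",
        "housekeeping": outdir / "housekeeping_kos.txt",
    }
    for key in ("curves", "samples", "transcripts", "species_map",
                "species_counts", "gene_map", "species_metadata"):
        getattr(exp, key).to_csv(paths[key], sep="\t", index=False)
    exp.protein_hits.to_csv(paths["protein_hits"], sep="\t", index=False, header=False)
    exp.nucleotide_hits.to_csv(paths["nucleotide_hits"], sep="\t", index=False, header=False)
    exp.truth.to_json(paths["truth"])
    paths["housekeeping"].write_text("\n".join(sorted(exp.truth.hk_ko_ids)) + "\n")
    return paths
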