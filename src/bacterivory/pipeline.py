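"""End-to-end pipeline: simulate (or load) inputs, then run every analysis
stage and write its tables. All outputs are plain TSV; given the same
configuration and seed the run is byte-identical."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import community, detection, foldchange, quant, states, trophic
from .config import SimulationConfig
from .simulate import SimulatedExperiment, simulate_all, write_experiment


@dataclass
class PipelineResult:
    experiment: SimulatedExperiment
    states: pd.DataFrame
    ordination: pd.DataFrame
    ko_table: pd.DataFrame
    grouped_table: pd.DataFrame
    highly_expressed: set[str]
    fold_changes: pd.DataFrame
    fc_flags: set[str]
    candidates: pd.DataFrame
    cpm_long: pd.DataFrame
    species_totals: pd.DataFrame
    observations: pd.DataFrame
    test_results: pd.DataFrame
    markers: pd.DataFrame


def run_all(
    config: SimulationConfig,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_perm: int = 10000,
    min_tpm: float = 2.0,
    min_mean_tpm: float = 500.0,
    overlap_threshold: float = 50.0,
    onset_ratio: float = 2.0,
    epsilon: float = 0.01,
    min_incubations: int = 3,
    min_n: int = 15,
    alpha: float = 0.05,
    imbalance_ratio: float = 5.0,
) -> PipelineResult:
    """Simulate one experiment and push it through every analysis stage."""
    exp = simulate_all(config, seed)

    # growth states from the (noisy) counts, validated by ordination
    state_table = states.classify_all_incubations(
        exp.curves, exp.samples[["sample_id", "incubation", "time_days"]],
        onset_ratio=onset_ratio)
    counts = exp.transcripts.set_index("transcript_id")[list(state_table["sample_id"])]
    ordination = states.validate_states_pca(counts, state_table)

    # community expression
    expressed = community.filter_expressed(exp.transcripts, min_tpm=min_tpm)
    ko_table, ko_transcripts = community.pool_kos(expressed)
    overlap = community.compute_ko_overlap(
        {k: v for k, v in ko_transcripts.items() if len(v) > 0})
    groups = community.group_overlapping_kos(overlap, threshold=overlap_threshold)
    grouped = community.pool_groups(expressed, groups, ko_transcripts)
    highly = community.select_highly_expressed(grouped, state_table,
                                               min_mean_tpm=min_mean_tpm)
    hk, _missing = community.load_housekeeping(sorted(exp.truth.hk_ko_ids), grouped)

    # fold change vs housekeeping baseline
    fcs = foldchange.compute_fold_changes(grouped, state_table, hk, epsilon=epsilon)
    flags = foldchange.flag_candidates(fcs, min_incubations=min_incubations)

    # species detection and quantification
    candidates, _assign = detection.detect_species(
        exp.protein_hits, exp.nucleotide_hits, exp.species_map)
    cpm_long, totals = quant.quantify_species(exp.species_counts)

    # trophic comparison and final markers
    obs = trophic.relative_expression(
        cpm_long, totals, exp.gene_map[["cds_id", "gene"]], exp.species_metadata)
    results = trophic.test_all_genes(obs, n_perm=n_perm, min_n=min_n, alpha=alpha,
                                     imbalance_ratio=imbalance_ratio, seed=seed)
    markers = trophic.select_markers(results, flags)

    result = PipelineResult(exp, state_table, ordination, ko_table, grouped, highly,
                            fcs, flags, candidates, cpm_long, totals, obs,
                            results, markers)
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated inputs and every stage's output tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_experiment(result.experiment, outdir / "inputs")

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    _write(result.states, "sample_states.tsv")
    _write(result.ordination, "state_ordination.tsv")
    _write(result.ko_table, "ko_table.tsv", index=True)
    _write(result.grouped_table, "ko_groups_table.tsv", index=True)
    _write(pd.DataFrame({"gene_id": sorted(result.highly_expressed)}),
           "highly_expressed.tsv")
    _write(result.fold_changes, "fold_changes.tsv")
    _write(pd.DataFrame({"gene_id": sorted(result.fc_flags)}), "fc_flagged.tsv")
    _write(result.candidates, "species_candidates.tsv")
    _write(result.cpm_long, "species_cpm.tsv")
    _write(result.species_totals, "species_totals.tsv", index=True)
    _write(result.observations, "relative_expression.tsv")
    _write(result.markers, "trophic_markers.tsv")
    return paths
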