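"""End-to-end orchestration: load or simulate, preprocess, network, tests.

Stage order: load/generate -> log transform -> missingness filter ->
normalize -> outlier removal -> baseline-sample selection -> network build
(modules, eigenproteins, hubs, stability) -> eigenprotein group tests ->
differential correlation per disease group -> enrichment of dyscorrelated
foregrounds -> longitudinal screen on all visits -> enrichment of
rising/falling foregrounds -> optional cross-tabulation against a second
network's module assignment.  Each artifact is written as TSV next to a
single JSON summary; one global seed is fanned out deterministically to
per-stage child seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import AbundanceMatrix, GeneMap, SampleInfo, metadata_frame
from . import io as cio
from .preprocess import (
    detect_outlier_samples,
    filter_missing_by_group,
    log_transform,
    normalize,
    select_background,
)
from .network import NetworkConfig, build_network, edge_list, module_stability
from .differential import (
    differential_correlation_table,
    eigenprotein_group_tests,
    group_correlation_profiles,
)
from .enrichment import cross_tabulation, hypergeometric_enrichment, module_gene_sets
from .longitudinal import longitudinal_screen
from .synthetic import SyntheticConfig, default_study_fixture, generate

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("csfnet.pipeline")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    out_dir: str = "csfnet_out"
    abundance_path: str | None = None
    metadata_path: str | None = None
    gene_map_path: str | None = None
    gene_sets_path: str | None = None
    synthetic: str | SyntheticConfig | None = None  # "default" or a SyntheticConfig
    orientation: str = "proteins_in_rows"
    input_scale: str = "linear"
    reference_group: str = "HC"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    max_missing_frac: float = 0.5
    background_frac: float = 0.9
    outlier_z_cut: float = 3.0
    alpha: float = 0.1
    hub_frac: float = 0.10
    stability_iterations: int = 0
    min_longitudinal_subjects: int = 5
    longitudinal_group: str | None = None
    cross_assignment_path: str | None = None
    edge_min_abs_r: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and (self.abundance_path is None or self.metadata_path is None):
            raise ValueError("config needs either input paths or a synthetic spec")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("abundance_path", "metadata_path", "gene_map_path",
                     "gene_sets_path", "cross_assignment_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file; nested ``network`` keys populate NetworkConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    net = NetworkConfig(**raw.pop("network", {}))
    return PipelineConfig(network=net, **raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write artifacts; returns the JSON summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    summary: dict = {
        "schema_version": 1,
        "software_version": __version__,
        "seed": config.seed,
        "stage_seeds": {"synthetic": seeds[0], "stability": seeds[1]},
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return summary["stages"].setdefault(name, {})

    # ---- load / generate -------------------------------------------------
    st = stage("load")
    gene_map: GeneMap | None = None
    gene_sets = None
    if config.synthetic is not None:
        if config.synthetic == "default":
            matrix, metadata, truth = default_study_fixture(seed=seeds[0])
        elif isinstance(config.synthetic, SyntheticConfig):
            matrix, metadata, truth = generate(config.synthetic)
        else:
            raise ValueError("synthetic must be 'default' or a SyntheticConfig")
        with open(out / "synthetic_truth.json", "w") as fh:
            json.dump(truth.to_jsonable(), fh)
        cio.write_abundance(matrix, out / "abundance_raw.tsv")
        cio.write_metadata(metadata, out / "metadata.tsv")
    else:
        matrix = cio.read_abundance(
            config.abundance_path, orientation=config.orientation, scale=config.input_scale
        )
        metadata = cio.read_metadata(config.metadata_path)
        only_m, only_meta = cio.orphan_samples(matrix, metadata)
        if only_m or only_meta:
            log.warning("orphan samples: matrix-only %s, metadata-only %s",
                        sorted(only_m), sorted(only_meta))
            st["orphans"] = {"matrix_only": sorted(only_m), "metadata_only": sorted(only_meta)}
            matrix = matrix.subset_samples([s for s in matrix.sample_ids if s not in only_m])
            metadata = [r for r in metadata if r.sample_id in set(matrix.sample_ids)]
    if config.gene_map_path:
        gene_map = cio.read_gene_map(config.gene_map_path)
    if config.gene_sets_path:
        gene_sets = cio.read_gmt(config.gene_sets_path)
    st.update({"n_proteins": matrix.n_proteins, "n_samples": matrix.n_samples})

    # ---- preprocessing ---------------------------------------------------
    st = stage("preprocess")
    if matrix.scale == "linear":
        matrix = log_transform(matrix)
    matrix, miss_report = filter_missing_by_group(matrix, metadata, config.max_missing_frac)
    background = select_background(matrix, config.background_frac)
    matrix, norm_report = normalize(matrix, background)
    flagged, outlier_report = detect_outlier_samples(matrix, z_cut=config.outlier_z_cut)
    matrix = matrix.subset_samples([s for s in matrix.sample_ids if s not in flagged])
    metadata = [r for r in metadata if r.sample_id in set(matrix.sample_ids)]
    st.update(
        {
            "proteins_removed_missingness": len(miss_report.excluded_proteins),
            "n_background": len(background),
            "outlier_samples": sorted(flagged),
            "n_proteins": matrix.n_proteins,
            "n_samples": matrix.n_samples,
        }
    )
    pd.DataFrame(
        [
            {"protein_id": p, **{f"missing_frac_{g}": v for g, v in fr.items()}}
            for p, fr in miss_report.excluded_proteins.items()
        ]
    ).to_csv(out / "excluded_proteins.tsv", sep="\t", index=False)
    with open(out / "preprocess_report.json", "w") as fh:
        json.dump(
            {
                "missingness": miss_report.to_jsonable(),
                "normalization": norm_report.to_jsonable(),
                "outliers": outlier_report.to_jsonable(),
            },
            fh,
        )
    cio.write_abundance(matrix, out / "abundance_normalized.tsv")

    # ---- baseline selection + network -----------------------------------
    st = stage("network")
    meta_df = metadata_frame(metadata)
    baseline_ids = [s for s in matrix.sample_ids if int(meta_df.loc[s, "visit"]) == 1]
    baseline = matrix.subset_samples(baseline_ids)
    net = build_network(baseline, config.network)
    if config.stability_iterations > 0:
        net.stability = module_stability(
            baseline, config.network, n_iter=config.stability_iterations,
            seed=seeds[1], reference=net,
        )
    kin, hub = net.kin, net.hub
    modules_df = pd.DataFrame(
        {
            "protein_id": net.protein_ids,
            "module": net.module_assignment,
            "kin": kin,
            "hub": hub,
            "stability": net.stability if net.stability is not None else np.nan,
        }
    )
    modules_df.to_csv(out / "modules.tsv", sep="\t", index=False)
    eig_df = pd.DataFrame(
        net.eigenproteins,
        index=[f"M{m}" for m in range(1, net.n_modules + 1)],
        columns=net.sample_ids,
    )
    eig_df.to_csv(out / "eigenproteins.tsv", sep="\t")
    pd.DataFrame(edge_list(net, config.edge_min_abs_r),
                 columns=["protein_a", "protein_b", "r", "adjacency"]).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    st.update(
        {
            "n_baseline_samples": baseline.n_samples,
            "n_modules": net.n_modules,
            "module_sizes": [int((net.module_assignment == m).sum())
                             for m in range(1, net.n_modules + 1)],
            "n_unassigned": int((net.module_assignment == 0).sum()),
            "variance_explained": [round(float(v), 4) for v in net.variance_explained],
        }
    )

    # ---- eigenprotein group tests ---------------------------------------
    st = stage("eigenprotein_tests")
    baseline_meta = [r for r in metadata if r.sample_id in set(baseline_ids)]
    ep_tests = eigenprotein_group_tests(
        net.eigenproteins, baseline.sample_ids, baseline_meta, config.reference_group
    )
    pd.DataFrame([vars(t) for t in ep_tests]).to_csv(
        out / "eigenprotein_tests.tsv", sep="\t", index=False
    )
    st["n_tests"] = len(ep_tests)
    st["significant_raw_p05"] = sum(t.p_value < 0.05 for t in ep_tests)

    # ---- differential correlation per disease group ----------------------
    st = stage("differential_correlation")
    groups = [g for g in dict.fromkeys(r.group for r in baseline_meta)
              if g != config.reference_group]
    r_ref, n_ref = group_correlation_profiles(
        baseline, baseline_meta, config.reference_group, config.network.min_pairwise_n
    )
    assignment_map = dict(zip(net.protein_ids, net.module_assignment))
    module_sets_prot = {
        m: set(net.module_members(m)) for m in range(1, net.n_modules + 1)
    }
    dyscorrelated: dict[str, set[str]] = {}
    for g in groups:
        r_g, n_g = group_correlation_profiles(
            baseline, baseline_meta, g, config.network.min_pairwise_n
        )
        table = differential_correlation_table(
            r_ref, n_ref, r_g, n_g, baseline.protein_ids, alpha=config.alpha
        )
        table = table.sort_values("p_adjusted", kind="stable")
        table.to_csv(out / f"diffcorr_{g}.tsv", sep="\t", index=False)
        sig = table[table["significant"]]
        dyscorrelated[g] = set(sig["protein_i"]) | set(sig["protein_j"])
        st[g] = {"n_pairs_tested": len(table), "n_significant": int(len(sig)),
                 "n_proteins": len(dyscorrelated[g])}

    # ---- enrichment of dyscorrelated foregrounds -------------------------
    st = stage("enrichment_dyscorrelated")
    background_ids = set(net.protein_ids)
    for g, fg in dyscorrelated.items():
        recs = hypergeometric_enrichment(fg, background_ids, module_sets_prot, config.alpha)
        pd.DataFrame([vars(r) for r in recs]).to_csv(
            out / f"enrichment_dyscorr_{g}.tsv", sep="\t", index=False
        )
        st[g] = {"n_foreground": len(fg)}
        if gene_sets is not None and gene_map is not None:
            fg_genes = {gene_map[p] for p in fg if p in gene_map}
            bg_genes = {gene_map[p] for p in background_ids if p in gene_map}
            recs = hypergeometric_enrichment(fg_genes, bg_genes, gene_sets, config.alpha)
            pd.DataFrame([vars(r) for r in recs]).to_csv(
                out / f"geneset_enrichment_dyscorr_{g}.tsv", sep="\t", index=False
            )

    # ---- longitudinal screen (all visits) --------------------------------
    st = stage("longitudinal")
    lg = config.longitudinal_group
    try:
        records = longitudinal_screen(
            matrix, metadata, alpha=config.alpha,
            min_subjects=config.min_longitudinal_subjects, group=lg,
        )
    except ValueError as exc:
        log.warning("longitudinal screen skipped: %s", exc)
        records = []
    if records:
        long_df = pd.DataFrame(
            [{**vars(r.fit), "p_adjusted": r.p_adjusted, "direction": r.direction}
             for r in records]
        ).sort_values("p_adjusted", kind="stable")
        long_df.to_csv(out / "longitudinal.tsv", sep="\t", index=False)
        rising = {r.fit.protein_id for r in records if r.direction == "increasing"}
        falling = {r.fit.protein_id for r in records if r.direction == "decreasing"}
        st.update({"n_fitted": len(records), "n_increasing": len(rising),
                   "n_decreasing": len(falling)})
        for name, fg in (("increasing", rising), ("decreasing", falling)):
            fg = fg & background_ids
            recs = hypergeometric_enrichment(fg, background_ids, module_sets_prot, config.alpha)
            pd.DataFrame([vars(r) for r in recs]).to_csv(
                out / f"enrichment_longitudinal_{name}.tsv", sep="\t", index=False
            )

    # ---- optional cross-tabulation ---------------------------------------
    if config.cross_assignment_path:
        st = stage("cross_tabulation")
        other = pd.read_csv(config.cross_assignment_path, sep="\t")
        other_assignment = dict(zip(other.iloc[:, 0].astype(str), other.iloc[:, 1].astype(int)))
        ct = cross_tabulation(assignment_map, other_assignment,
                              gene_map_a=gene_map, gene_map_b=gene_map)
        rows = [
            {"module_a": ma, "module_b": mb, **vars(rec)}
            for (ma, mb), rec in ct.records.items()
        ]
        pd.DataFrame(rows).to_csv(out / "cross_tabulation.tsv", sep="\t", index=False)
        pd.DataFrame(ct.neg_log10_p(),
                     index=[f"A{m}" for m in ct.modules_a],
                     columns=[f"B{m}" for m in ct.modules_b]).to_csv(
            out / "cross_tabulation_neglog10p.tsv", sep="\t"
        )
        st["n_cells"] = len(ct.records)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
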