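"""End-to-end orchestration: SSI -> quadrants -> screen -> Jacobians -> dJ.

``run_pipeline`` wires the stages together from a :class:`PipelineConfig`,
writes every artifact as TSV plus a JSON run manifest, and is deterministic
given the manifest: re-running an identical configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import correlate_to_ssi, log_transform
from .io import read_abundance_table, read_network, read_phenotype_table
from .jacobian import (
    JacobianMask,
    classify_edges,
    differential_jacobian,
    estimate_covariance,
    monte_carlo_jacobian,
)
from .ssi import classify_quadrants, compute_ssi
from .types import MetabolicNetwork

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("metabojac")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from flat key=value text."""

    abundance_path: str = ""
    phenotype_path: str = ""
    network_path: str = ""
    out_dir: str = "metabojac_out"
    # analysis slice
    condition: str = "DS"
    time_point: int = 2
    # group definitions: quadrant labels computed in-run, or explicit lists
    group1_quadrant: str = "Q1"
    group2_quadrant: str = "Q3"
    group1_genotypes: list[str] = field(default_factory=list)
    group2_genotypes: list[str] = field(default_factory=list)
    # jacobian settings
    n_iter: int = 10_000
    seed: int = 0
    noise_mode: str = "halfnormal"
    epsilon_factor: float = 1e-9
    shrinkage: float = 0.0
    metabolite_subset: list[str] = field(default_factory=list)
    edge_threshold: float = 0.0
    # association settings
    log_base: str = "e"
    alpha: float = 0.05
    nonpositive_policy: str = "error"
    # ssi settings
    ssi_threshold: float = 1.0
    trait_threshold_policy: str = "median"
    trait_threshold: float | None = None

    _LIST_KEYS = ("group1_genotypes", "group2_genotypes", "metabolite_subset")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file ('#' starts a comment).

        List-valued keys take comma-separated values; unknown keys raise.
        """
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in cls._LIST_KEYS:
                kwargs[key] = [v.strip() for v in raw.split(",") if v.strip()]
            else:
                ftype = fields[key].type
                if "int" in str(ftype):
                    kwargs[key] = int(raw)
                elif "float" in str(ftype):
                    kwargs[key] = float(raw) if raw.lower() != "none" else None
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Reproducibility record emitted with every run (no timestamps)."""

    version: str
    config: dict
    stage_counts: dict
    seeds: dict
    warnings: list[str]
    residuals: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _assemble_network(
    network: MetabolicNetwork, metabolites: list[str]
) -> MetabolicNetwork:
    """Re-key the network onto the metabolite universe (assembly check)."""
    unmatched = sorted(set(network.names) - set(metabolites))
    if unmatched:
        raise ValueError(
            f"network references metabolites absent from the abundance "
            f"table: {unmatched}"
        )
    self_edges = [e for e in network.edges if e[0] == e[1]]
    if self_edges:
        logger.info("network contains %d self-edge(s); diagonal is free anyway",
                    len(self_edges))
    return MetabolicNetwork(names=list(metabolites), edges=list(network.edges))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Stages: SSI -> quadrant classification -> metabolite-SSI screen ->
    per-group covariance -> Monte-Carlo Jacobians -> differential Jacobian
    -> edge report. Outputs: ssi.tsv, quadrants.tsv, correlations.tsv,
    jacobian_<group>_{median,iqr}.tsv, differential_edges.tsv,
    manifest.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    counts: dict = {}

    matrix = read_abundance_table(config.abundance_path)
    phenotype = read_phenotype_table(config.phenotype_path)
    raw_network = read_network(config.network_path)
    counts["abundance_observations"] = matrix.n_observations
    counts["metabolites"] = len(matrix.metabolites)
    counts["phenotype_genotypes"] = len(phenotype)
    logger.info("loaded %d observations x %d metabolites, %d genotypes",
                matrix.n_observations, len(matrix.metabolites), len(phenotype))

    # --- SSI and quadrants -------------------------------------------------
    ssi = compute_ssi(phenotype)
    quadrants = classify_quadrants(
        ssi,
        phenotype,
        ssi_threshold=config.ssi_threshold,
        trait_threshold_policy=config.trait_threshold_policy,
        trait_threshold=config.trait_threshold,
    )
    ssi_out = ssi.table.copy()
    ssi_out["quadrant"] = quadrants.table["quadrant"]
    ssi_out.to_csv(out_dir / "ssi.tsv", sep="\t", index=False)
    quadrants.table.to_csv(out_dir / "quadrants.tsv", sep="\t", index=False)
    summary = {
        "SI": ssi.SI, "MYp": ssi.MYp, "MYs": ssi.MYs,
        "ssi_threshold": quadrants.ssi_threshold,
        "trait_threshold": quadrants.trait_threshold,
    }
    (out_dir / "ssi_summary.json").write_text(
        json.dumps(summary, sort_keys=True) + "\n"
    )
    counts["genotypes_per_quadrant"] = (
        quadrants.table["quadrant"].value_counts().to_dict()
    )

    # --- association screen ------------------------------------------------
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        log_matrix = log_transform(
            matrix, base=config.log_base,
            nonpositive_policy=config.nonpositive_policy,
        )
        correlations = correlate_to_ssi(
            log_matrix, ssi,
            condition=config.condition, time_point=config.time_point,
            alpha=config.alpha,
        )
    caught.extend(str(w.message) for w in wlist)
    correlations.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    counts["metabolites_screened"] = len(correlations)

    # --- group definitions -------------------------------------------------
    if config.group1_genotypes:
        group1 = list(config.group1_genotypes)
    else:
        group1 = quadrants.members(config.group1_quadrant)
    if config.group2_genotypes:
        group2 = list(config.group2_genotypes)
    else:
        group2 = quadrants.members(config.group2_quadrant)
    for label, members in (("group 1", group1), ("group 2", group2)):
        if len(members) < 2:
            raise ValueError(f"group too small for covariance: {label} has "
                             f"{len(members)} genotype(s)")
    counts["group1_genotypes"] = len(group1)
    counts["group2_genotypes"] = len(group2)

    # --- per-group covariance and Monte-Carlo Jacobians --------------------
    subset = list(config.metabolite_subset) or list(matrix.metabolites)
    network = _assemble_network(raw_network, subset)
    mask = JacobianMask.from_network(network)
    if mask.n_free == mask.n:
        msg = "mask has no off-diagonal freedom; proceeding diagonal-only"
        warnings.warn(msg, stacklevel=2)
        caught.append(msg)

    estimates = {}
    residuals: dict = {}
    for tag, members in (("group1", group1), ("group2", group2)):
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            C = estimate_covariance(
                log_matrix.frame, genotypes=members,
                condition=config.condition, time_point=config.time_point,
                metabolites=subset,
            )
        caught.extend(str(w.message) for w in wlist)
        if config.shrinkage > 0:
            lam = config.shrinkage
            C.values = (1 - lam) * C.values + lam * np.diag(np.diag(C.values))
        est = monte_carlo_jacobian(
            C, mask, n_iter=config.n_iter, seed=config.seed,
            noise=config.noise_mode,
        )
        estimates[tag] = est
        residuals[tag] = {
            "median_residual_norm": float(np.median(est.residual_norms)),
            "rank_deficiency": est.rank_deficiency,
            "n_samples": C.n_samples,
        }
        for kind, mat in (("median", est.median), ("iqr", est.iqr)):
            pd.DataFrame(mat, index=mask.names, columns=mask.names).to_csv(
                out_dir / f"jacobian_{tag}_{kind}.tsv", sep="\t",
                index_label="metabolite",
            )

    # --- differential Jacobian and edge report -----------------------------
    diff = differential_jacobian(
        estimates["group1"], estimates["group2"],
        epsilon_factor=config.epsilon_factor,
    )
    edges = classify_edges(
        diff, threshold=config.edge_threshold,
        group_labels=(config.group1_quadrant or "group1",
                      config.group2_quadrant or "group2"),
    )
    edges.to_csv(out_dir / "differential_edges.tsv", sep="\t", index=False)
    counts["differential_edges_reported"] = len(edges)

    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(
        version=__version__,
        config=cfg_dict,
        stage_counts=counts,
        seeds={"jacobian": config.seed},
        warnings=caught,
        residuals=residuals,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    for msg in caught:
        logger.warning("%s", msg)
    return manifest
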