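"""End-to-end analysis runs with reproducible provenance.

A run builds the gene-centric network from a reaction table (with the
chosen currency treatment and mapping variant), maps each background's
differential-expression calls onto it, and computes the metabolic
coherence; optionally it adds the TRN statistics (digital CTC and
sign consistency) and the FBA stages (activity-filtered MC and the
medium-reduction scan).  Every output embeds the seeds and a hash of
the configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as mio
from .coherence import DEFAULT_N_REALIZATIONS, jackknife_mc, mc_zscore
from .fba import (
    DEFAULT_FLUX_TOL,
    active_reaction_set,
    filter_gene_network_by_activity,
    mc_vs_medium_curve,
    reaction_network_from_flux_model,
    solve_fba,
)
from .network import (
    MappingVariant,
    build_reaction_adjacency,
    flag_currency_by_degree,
    project_to_genes,
)
from .trn import digital_ctc, filter_trn_to_metabolic, trn_consistency_zscore

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration, caught before any computation."""


@dataclass
class RunConfig:
    reaction_table: str
    expression_tables: dict[str, str]  # background -> path
    variant: str = "all"
    currency_mode: str = "none"  # "list" | "degree" | "none"
    currency_list: str | None = None
    degree_fraction: float = 0.04
    n_realizations: int = DEFAULT_N_REALIZATIONS
    seed: int = 0
    trn_table: str | None = None
    trn_enabled: bool = False
    fba_model: str | None = None  # SBML or TSV (by extension)
    medium: str | None = None
    fba_enabled: bool = False
    medium_scan_enabled: bool = False
    n_trajectories: int = 20
    flux_tol: float = DEFAULT_FLUX_TOL
    parsimonious: bool = True
    jackknife: bool = False
    jackknife_repeats: int = 100
    jackknife_drop: float = 0.10
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        def need(path: str | None, what: str) -> None:
            if path is None:
                raise ConfigError(f"{what} is enabled but no path configured")
            if not Path(path).exists():
                raise ConfigError(f"{what} path does not exist: {path}")

        need(self.reaction_table, "reaction table")
        if not self.expression_tables:
            raise ConfigError("no expression tables configured")
        for background, path in self.expression_tables.items():
            need(path, f"expression table for {background!r}")
        try:
            MappingVariant(self.variant)
        except ValueError:
            raise ConfigError(f"unknown mapping variant {self.variant!r}") from None
        if self.currency_mode not in {"list", "degree", "none"}:
            raise ConfigError(f"unknown currency mode {self.currency_mode!r}")
        if self.currency_mode == "list":
            need(self.currency_list, "currency list")
        if self.trn_enabled:
            need(self.trn_table, "TRN table")
        if self.fba_enabled or self.medium_scan_enabled:
            need(self.fba_model, "FBA model")
            need(self.medium, "medium definition")

    def hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _build_gene_network(config: RunConfig):
    reactions = mio.read_reaction_table(config.reaction_table)
    if config.currency_mode == "list":
        currency = mio.read_currency_list(config.currency_list)
        net = build_reaction_adjacency(reactions, currency)
    elif config.currency_mode == "degree":
        base = build_reaction_adjacency(reactions)
        currency = flag_currency_by_degree(base, config.degree_fraction)
        net = build_reaction_adjacency(reactions, currency)
    else:
        net = build_reaction_adjacency(reactions)
    gene_net = project_to_genes(
        net, config.variant, provenance=Path(config.reaction_table).stem
    )
    return net, gene_net


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and return the result bundle.

    The bundle is a JSON-serialisable dict: per-background coherence
    records, optional TRN and FBA sections, a provenance block (config
    hash, seeds, stage counts) and a log of genes discarded at each
    mapping step.  Any stage failure aborts with the stage name and a
    machine-readable code.
    """
    config.validate()

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(
                        f"stage {name!r} failed [stage_error:{name}]: {exc}"
                    ) from exc

        return _Stage()

    results: dict = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_realizations": config.n_realizations,
            "variant": config.variant,
            "currency_mode": config.currency_mode,
        },
        "coherence": {},
        "log": {},
    }

    with stage("build-net"):
        reaction_net, gene_net = _build_gene_network(config)
        results["log"]["n_reactions"] = len(reaction_net.reactions)
        results["log"]["n_genes"] = len(gene_net.nodes)
        results["log"]["n_gene_edges"] = len(gene_net.edges)

    calls_by_background = {
        background: mio.read_expression_calls(path, background=background)
        for background, path in config.expression_tables.items()
    }

    with stage("coherence"):
        for background, calls in calls_by_background.items():
            res = mc_zscore(
                gene_net, calls,
                n_realizations=config.n_realizations, seed=config.seed,
            )
            record = res.to_record()
            if config.jackknife:
                jk = jackknife_mc(
                    gene_net, calls,
                    n_repeats=config.jackknife_repeats,
                    drop_fraction=config.jackknife_drop,
                    seed=config.seed,
                    n_realizations=config.n_realizations,
                )
                record["jackknife_sd"] = jk.sd
                record["jackknife_missing"] = jk.n_missing_repeats
            results["coherence"][background] = record

    if config.trn_enabled:
        with stage("trn"):
            trn = filter_trn_to_metabolic(
                mio.read_trn_table(config.trn_table), gene_net.nodes
            )
            results["trn"] = {}
            for background, calls in calls_by_background.items():
                entry = {}
                entry["digital_ctc"] = digital_ctc(
                    trn, calls,
                    n_realizations=config.n_realizations, seed=config.seed,
                ).to_record()
                try:
                    entry["consistency"] = trn_consistency_zscore(
                        trn, calls,
                        n_realizations=config.n_realizations, seed=config.seed,
                    ).to_record()
                except ValueError:
                    entry["consistency"] = None
                results["trn"][background] = entry

    if config.fba_enabled or config.medium_scan_enabled:
        with stage("fba-filter"):
            model_path = Path(config.fba_model)
            if model_path.suffix.lower() in {".xml", ".sbml"}:
                model = mio.read_sbml_model(model_path)
            else:
                model = mio.read_flux_model_tsv(model_path)
            medium = mio.read_medium(config.medium)
            model_net = reaction_network_from_flux_model(model)
            model_gene_net = project_to_genes(
                model_net, config.variant, provenance=model_path.stem
            )
            sol = solve_fba(
                model, medium,
                parsimonious=config.parsimonious, tol=config.flux_tol,
            )
            results["fba"] = {
                "status": sol.status,
                "biomass": sol.objective_value,
                "filtered_coherence": {},
            }
            if sol.optimal:
                active = active_reaction_set(sol, tol=config.flux_tol)
                filtered = filter_gene_network_by_activity(
                    model_gene_net, model, active
                )
                results["fba"]["n_active_reactions"] = len(active)
                results["fba"]["n_active_genes"] = len(filtered.nodes)
                for background, calls in calls_by_background.items():
                    try:
                        rec = mc_zscore(
                            filtered, calls,
                            n_realizations=config.n_realizations, seed=config.seed,
                        ).to_record()
                    except ValueError:
                        rec = None
                    results["fba"]["filtered_coherence"][background] = rec

        if config.medium_scan_enabled:
            with stage("medium-scan"):
                curve = mc_vs_medium_curve(
                    model, model_gene_net, calls_by_background, medium,
                    n_trajectories=config.n_trajectories,
                    seed=config.seed,
                    n_realizations=config.n_realizations,
                    tol=config.flux_tol,
                )
                results["medium_scan"] = curve.to_dict(orient="records")

    return results
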