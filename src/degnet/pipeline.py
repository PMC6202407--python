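"""End-to-end orchestration: normalize -> test -> pattern -> enrich -> network.

A single YAML config drives the whole analysis. Exactly one of a ``real``
input block (expression TSV + design TSV, optional probe map) or a
``synthetic`` block (generator parameters) must be present; thresholds,
permutation scope, the optional FDR switch and the probe-collapse rule are
all surfaced in the config. The settings matching the original study design
are available as the named preset ``paper2018``:

    thresholds:   alpha 0.05, |log2FC| >= 1 (boundary-inclusive)
    statistics:   pooled-variance T, within-contrast exhaustive balanced
                  permutations, Gaussian-KDE empirical null, no extra FDR
    enrichment:   EASE score, enriched at p < 0.05, array background

The run writes per-contrast DEG tables, the pattern/group table, enrichment
tables, network files, a heatmap, and a JSON run report with per-contrast DEG
counts, cluster count, group sizes, seeds and a config echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import network as net
from . import patterning as pat
from . import preprocess as pre
from . import stats as st
from . import synthetic as syn
from .errors import DegnetError, ParameterError

logger = logging.getLogger(__name__)

#: Analysis settings mirroring the original study (see module docstring).
PRESETS = {
    "paper2018": {
        "alpha": 0.05,
        "lfc": 1.0,
        "fdr_adjust": False,
        "permutation_scope": "within",
        "collapse_rule": "max_mean",
        "enrich_alpha": 0.05,
    },
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for semantics)."""

    outdir: str
    real: dict | None = None
    synthetic: dict | None = None
    alpha: float = 0.05
    lfc: float = 1.0
    fdr_adjust: bool = False
    permutation_scope: str = "within"
    enrich_alpha: float = 0.05
    gmt: str | None = None
    interactions: str | None = None
    pathway_membership: str | None = None
    process_terms: list[str] = dataclasses.field(default_factory=list)
    pathways: list[str] = dataclasses.field(
        default_factory=lambda: list(net.DEFAULT_PATHWAYS))
    seed: int = 0
    preset: str | None = None

    def __post_init__(self) -> None:
        if (self.real is None) == (self.synthetic is None):
            raise ParameterError(
                "config must have exactly one of a 'real' or 'synthetic' block"
            )
        if self.alpha <= 0 or self.lfc < 0:
            raise ParameterError("thresholds must be positive")
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ParameterError(f"unknown preset {self.preset!r}")
            for key, value in PRESETS[self.preset].items():
                if key != "collapse_rule":
                    setattr(self, key, value)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: PipelineConfig):
    """Return (matrix, design, truth-or-None) from the configured source."""
    if config.real is not None:
        block = config.real
        matrix = pre.read_expression(block["expression"])
        design = syn.read_design(block["design"])
        if block.get("raw_intensities", False):
            matrix = np.log2(matrix)
        if block.get("probe_map"):
            pm = pre.read_probe_map(block["probe_map"])
            matrix = pre.collapse_probes(matrix, pm)
        return matrix, design, None
    block = dict(config.synthetic)
    design = syn.make_design(
        replicates=int(block.pop("replicates", 2)),
        conditions=tuple(block.pop("conditions", syn.DEFAULT_CONDITIONS)),
    )
    n_genes = int(block.pop("n_genes", 1000))
    seed = int(block.pop("seed", config.seed))
    matrix, truth = syn.simulate_dataset(n_genes, design, seed=seed, **block)
    return matrix, design, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON).

    Any stage failure is re-raised annotated with the stage name; outputs
    written before the failure remain on disk and the report is not written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        matrix, design, truth = _load_inputs(config)

        stage = "normalize"
        norm = pre.quantile_normalize(matrix)
        pre.write_expression(norm, outdir / "normalized.tsv")

        stage = "deg_test"
        stats = st.run_all_contrasts(
            norm, design, alpha=config.alpha, lfc=config.lfc,
            fdr_adjust=config.fdr_adjust,
            permutation_scope=config.permutation_scope,
        )
        for cname, table in stats.items():
            st.write_contrast_table(table, outdir / f"deg_{cname}.tsv")

        stage = "patterning"
        patterns = pat.assign_patterns(stats)
        pat.write_patterns(patterns, outdir / "patterns.tsv")
        if len(patterns) >= 2:
            lfc = pd.DataFrame(
                {c: stats[c].loc[patterns.index, "log2fc"] for c in stats}
            )
            order = pat.hierarchical_order(lfc)
            pat.plot_heatmap(lfc, outdir / "heatmap.png", order=order)

        enrich_table = None
        if config.gmt:
            stage = "enrichment"
            collection = enr.read_gmt(config.gmt)
            background = list(norm.index)
            enrich_table = enr.enrich_groups(
                patterns, collection, background, alpha=config.enrich_alpha
            )
            enr.write_enrichment(enrich_table, outdir / "enrichment.tsv")

        network_report = None
        if config.interactions:
            stage = "network"
            records = net.read_interactions(config.interactions)
            if (config.process_terms and enrich_table is not None
                    and config.pathway_membership):
                membership = net.read_pathway_membership(
                    config.pathway_membership)
                genes = net.select_process_degs(
                    patterns, enrich_table, collection, config.process_terms,
                    membership, tuple(config.pathways),
                )
                pathway_of = dict(zip(
                    membership.iloc[:, 0], membership.iloc[:, 1]))
            else:
                genes = list(patterns.index)
                pathway_of = None
            if genes:
                model = net.build_network(genes, records, stats, pathway_of)
                for fmt in ("sif", "graphml", "json"):
                    net.export_network(model, outdir / f"network.{fmt}")
                network_report = {"nodes": len(model.nodes),
                                  "edges": len(model.edges)}
            else:
                network_report = {"nodes": 0, "edges": 0}
    except DegnetError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    report = {
        "contrasts": {
            c: {
                "total_degs": int((t["call"] != "ns").sum()),
                "up": int((t["call"] == "up").sum()),
                "down": int((t["call"] == "down").sum()),
            }
            for c, t in stats.items()
        },
        "n_genes": int(len(matrix)),
        "cluster_count": int(patterns["cluster"].nunique()),
        "group_sizes": pat.group_sizes(patterns),
        "network": network_report,
        "seed": int(config.seed),
        "config": config.echo(),
    }
    if truth is not None:
        planted = set(truth.planted_genes)
        called = set(patterns.index)
        report["synthetic_truth"] = {
            "planted_degs": len(planted),
            "recovered_planted": len(planted & called),
            "false_positives": len(called - planted),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def run_calibration(n_reps: int, n_genes: int, design: syn.StudyDesign,
                    seed: int, *, noise_sd: float = 0.25,
                    effects: tuple[float, ...] = (0.5, 1.0, 2.0),
                    deg_fraction: float = 0.1,
                    alpha: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
    """Monte-Carlo calibration of the DEG test on synthetic data.

    For each replicate: the empirical type-I error at ``alpha`` on a null
    dataset, and for each planted effect size the power (fraction of planted
    DEGs called) and sign accuracy (fraction of calls on planted DEGs whose
    direction matches the planted sign). One contrast (the design's first
    non-reference condition vs the reference) is evaluated. Seeds below 2^31
    are derived deterministically from ``seed``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    test_cond = design.contrast_conditions[0]
    contrast = st.Contrast(test_cond, design.reference)
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        null = syn.null_dataset(n_genes, design, noise_sd, rep_seed)
        table = st.run_contrast(null, design, contrast, alpha=alpha, lfc=lfc)
        row = {"rep": rep, "seed": rep_seed,
               "type_i_error": float((table["p_adj"] <= alpha).mean())}
        for effect in effects:
            eff_seed = int(rng.integers(0, 2**31 - 1))
            matrix, truth = syn.simulate_dataset(
                n_genes, design, deg_fraction=deg_fraction,
                effect_size=effect, noise_sd=noise_sd, seed=eff_seed,
            )
            table = st.run_contrast(matrix, design, contrast,
                                    alpha=alpha, lfc=lfc)
            planted = truth.signs[test_cond] != 0
            calls = table.loc[planted[planted].index, "call"]
            called = calls != "ns"
            signs = truth.signs.loc[called[called].index, test_cond]
            match = (calls[called] == signs.map({1: "up", -1: "down"}))
            row[f"power_{effect}"] = float(called.mean())
            row[f"sign_acc_{effect}"] = (
                float(match.mean()) if len(match) else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
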