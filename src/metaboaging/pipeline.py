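"""End-to-end orchestration: simulate -> preprocess -> trends -> network ->
influence -> lipids -> mortality -> fibers, with one config object and a
run manifest written next to the outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import influence, io, lipids, morphometry, mortality, network, preprocess, synthetic, trends

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one serializable object."""

    # synthetic inputs
    n_metabolites: int = 500
    n_per_group: int = 7
    effect_size: float = 2.0
    noise_sd: float = 0.3
    cohort_n: int = 10000
    n_fibers: int = 2000
    seed: int = 0
    # trends
    alpha: float = 0.05
    # network
    r_min: float = 0.7
    p_max: float = 0.01
    inflation: float = 2.0
    # influence
    ci_radius: int = 3
    top_k: int = 15
    # mortality
    max_inflections: int = 2
    smooth_window: int = 3
    # io
    out_dir: str = "results"
    abundance_path: str | None = None  # real inputs override simulation
    metadata_path: str | None = None
    survival_path: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Deterministic given the config seed.  Returns the in-memory bundle:
    trend calls and summary, network, modules, IVI ranks, lipid class
    summaries, mortality series and inflections, fiber categories.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    bundle: dict = {}

    # ---- inputs ------------------------------------------------------------
    if config.abundance_path:
        if not os.path.exists(config.abundance_path):
            raise FileNotFoundError(f"abundance input not found: {config.abundance_path}")
        table = io.read_abundance_table(config.abundance_path, config.metadata_path)
        truth = None
    else:
        specs = synthetic.default_trend_mixture(
            config.n_metabolites, config.effect_size, config.noise_sd
        )
        table, truth = synthetic.generate_abundance(
            specs, n_per_group=config.n_per_group, seed=config.seed
        )
        io.write_abundance_table(table, out("abundance.csv"), out("samples.csv"))
        truth.to_csv(out("truth.csv"))
    logger.info("stage=input metabolites=%d samples=%d", table.n_metabolites, table.n_samples)

    # ---- preprocess --------------------------------------------------------
    table = _stage("preprocess")(preprocess.deduplicate)(table)
    log2_table = _stage("preprocess")(preprocess.log_transform)(table, base=2)
    log10_table = _stage("preprocess")(preprocess.log_transform)(table, base=10)

    # ---- trends ------------------------------------------------------------
    calls, summary = _stage("trends")(trends.run_trend_analysis)(
        log2_table, trends.TrendConfig(alpha=config.alpha)
    )
    calls.to_csv(out("trend_calls.tsv"), sep="\t")
    with open(out("trend_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    bundle["trend_calls"], bundle["trend_summary"] = calls, summary
    logger.info("stage=trends metabolites=%d no_change=%.3f", len(calls), summary["no_change"])

    # ---- network + modules -------------------------------------------------
    net = _stage("network")(network.correlation_edges)(
        log10_table, r_min=config.r_min, p_max=config.p_max
    )
    for node in net.nodes:
        net.nodes[node]["trend_group"] = calls.at[node, "trend_group"]
    modules, converged = _stage("network")(network.mcl_cluster)(
        net, network.MclConfig(inflation=config.inflation)
    )
    io.write_network(net, out("network.graphml"), "graphml")
    pd.Series(modules, name="module").rename_axis("metabolite_id").to_csv(
        out("modules.tsv"), sep="\t"
    )
    bundle["network"], bundle["modules"] = net, modules
    logger.info(
        "stage=network nodes=%d edges=%d modules=%d converged=%s",
        net.number_of_nodes(), net.number_of_edges(), len(set(modules.values())), converged,
    )

    # ---- influence ---------------------------------------------------------
    cent = _stage("influence")(influence.centralities)(
        net, influence.IviConfig(ci_radius=config.ci_radius)
    )
    scores = influence.ivi(cent)
    top, group_counts = influence.rank_influential(
        scores, cent, calls, k=config.top_k
    )
    cent.assign(IVI=scores).to_csv(out("centrality_ivi.tsv"), sep="\t")
    top.to_csv(out("top_influential.tsv"), sep="\t")
    bundle["ivi"], bundle["top_influential"] = scores, top
    logger.info("stage=influence top_k=%d groups=%s", len(top), group_counts)

    # ---- lipids ------------------------------------------------------------
    annotations = lipids.annotate(table.metabolites["putative_name"])
    totals = _stage("lipids")(lipids.class_totals)(
        table, calls, annotations, alpha=config.alpha
    )
    dist = lipids.class_trend_distribution(calls, annotations)
    totals.to_csv(out("class_totals.tsv"), sep="\t")
    dist.to_csv(out("class_trend_distribution.tsv"), sep="\t")
    bundle["class_totals"], bundle["class_trend_distribution"] = totals, dist

    # ---- mortality ---------------------------------------------------------
    if config.survival_path:
        if not os.path.exists(config.survival_path):
            raise FileNotFoundError(f"survival input not found: {config.survival_path}")
        surv = io.read_survival(config.survival_path)
    else:
        surv = synthetic.generate_survival(
            synthetic.SurvivalSpec(n=config.cohort_n, seed=config.seed)
        )
        io.write_survival(surv, out("survival.csv"))
    series = _stage("mortality")(mortality.cumulative_mortality)(surv)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        inflections = _stage("mortality")(mortality.find_inflections)(
            series, max_points=config.max_inflections, smooth_window=config.smooth_window
        )
    pd.DataFrame(
        {"week": series.weeks, "M": series.mortality}
    ).assign(logM=lambda d: np.where(d.M > 0, np.log10(d.M.where(d.M > 0)), np.nan)).to_csv(
        out("mortality.tsv"), sep="\t", index=False
    )
    report = {
        "inflection_weeks": [e.x_hat for e in inflections],
        "phases": [list(p) for p in mortality.phases(series, inflections)],
    }
    with open(out("inflections.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    bundle["mortality_series"], bundle["inflections"] = series, inflections
    logger.info("stage=mortality inflection_weeks=%s", report["inflection_weeks"])

    # ---- fibers ------------------------------------------------------------
    areas = synthetic.generate_fiber_areas(
        config.n_fibers,
        components=((0.5, 800.0, 0.4), (0.35, 1600.0, 0.35), (0.15, 3200.0, 0.3)),
        seed=config.seed,
    )
    fibers, counts = _stage("fibers")(morphometry.classify_fibers)(areas)
    fibers.to_csv(out("fibers.csv"), index=False)
    pd.Series(counts, name="count").rename_axis("category").to_csv(
        out("fiber_counts.tsv"), sep="\t"
    )
    bundle["fibers"], bundle["fiber_counts"] = fibers, counts

    # ---- manifest ----------------------------------------------------------
    cfg_json = config.to_json()
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
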