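"""End-to-end analysis orchestration and community-size distribution fits.

Stage order is fixed: read -> directed census -> optional negative-link
completion -> reciprocal projection -> degree summary -> positive subnet ->
community detection -> signed communities -> perturbation metrics ->
size distribution fit -> negative hubs -> report.  One master seed controls
all randomness; Louvain-derived quantities are reported as means (with
standard deviations) over a run ensemble, deterministic leading-eigenvector
quantities as single values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .census import RelationshipCensus, classify_relationships, dunbar_ratio
from .completion import CompletionReport, complete_negative_links
from .detect import (
    Partition,
    louvain_partition,
    newman_partition,
    partition_similarity,
)
from .errors import PipelineError, UndefinedMetricError
from .graph import (
    DegreeSummary,
    DirectedSignedNetwork,
    degree_summary,
    read_signed_adjacency,
    read_signed_edgelist,
    reciprocal_projection,
    subnetwork_by_sign,
)
from .metrics import (
    DEFAULT_STABILITY_THRESHOLDS,
    MetricsReport,
    NegativeHubReport,
    SignedCommunitySet,
    build_signed_communities,
    metrics_report,
    negative_hubs,
)

# ---------------------------------------------------------------------------
# Exponential fit of the community-size distribution
# ---------------------------------------------------------------------------


@dataclass
class ExponentialFit:
    """Exponential model exp(-x/lambda) for the size CCDF; lambda is the
    mean community size."""

    lambda_hat: float
    r_squared: float
    method: str  # "least-squares-ccdf" | "mle"
    degenerate: bool = False


def fit_exponential_ccdf(
    sizes: list[float] | list[int], method: str = "least-squares-ccdf"
) -> ExponentialFit:
    """Fit exp(-x/lambda) to the empirical complementary CDF of sizes.

    Least-squares mode regresses log CCDF on x (intercept free, slope
    -1/lambda) at the observed sizes and reports R^2 on the CCDF scale.
    MLE mode returns the sample mean as lambda-hat.  At least 5 sizes are
    required; an all-equal sample is flagged degenerate.
    """
    if len(sizes) < 5:
        raise ValueError("need at least 5 sizes to fit a distribution")
    x = np.sort(np.asarray(sizes, dtype=float))
    n = x.size
    if np.allclose(x, x[0]):
        return ExponentialFit(float(x[0]), 0.0, method, degenerate=True)
    # empirical P(X >= x) evaluated at each observed size (unique values)
    ux, first_idx = np.unique(x, return_index=True)
    ccdf = 1.0 - first_idx / n  # count of samples >= ux[k], over n
    if method == "mle":
        lam = float(x.mean())
        yhat = np.exp(-ux / lam)
    elif method == "least-squares-ccdf":
        ly = np.log(ccdf)
        slope, intercept = np.polyfit(ux, ly, 1)
        if slope >= 0:
            return ExponentialFit(float(x.mean()), 0.0, method, degenerate=True)
        lam = -1.0 / slope
        yhat = np.exp(intercept + slope * ux)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    ss_res = float(np.sum((ccdf - yhat) ** 2))
    ss_tot = float(np.sum((ccdf - ccdf.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ExponentialFit(float(lam), float(r2), method)


# ---------------------------------------------------------------------------
# Configuration and report
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str | None = None
    input_format: str = "adjacency"  # "adjacency" | "edgelist"
    completion: bool = False
    completion_policy: str = "conservative"  # "conservative" | "permissive"
    method: str = "newman"  # "newman" | "louvain"
    gamma: float = 1.0
    runs: int = 1  # Louvain ensemble size
    seed: int = 0
    stability_thresholds: tuple[float, float] = DEFAULT_STABILITY_THRESHOLDS
    truncate: bool = True
    min_community_size: int = 2
    hub_threshold: int = 3
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stability_thresholds"] = list(self.stability_thresholds)
        return d


@dataclass
class AnalysisReport:
    config: dict
    version: str
    degree_summary: DegreeSummary
    census: RelationshipCensus
    dunbar_pos: float | None
    dunbar_neg: float | None
    completion: CompletionReport | None
    drop_report: dict
    partition: Partition
    signed_communities: SignedCommunitySet
    metrics: MetricsReport
    metrics_std: dict | None  # Louvain-ensemble dispersion, None for Newman
    ensemble_mean_similarity: float | None
    size_fit: ExponentialFit | None
    hubs: NegativeHubReport

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "degree_summary": dataclasses.asdict(self.degree_summary),
            "census": self.census.to_row(),
            "dunbar_pos": self.dunbar_pos,
            "dunbar_neg": self.dunbar_neg,
            "completion": self.completion.to_dict() if self.completion else None,
            "drop_report": self.drop_report,
            "n_communities": self.partition.K,
            "community_sizes": sorted(self.partition.sizes(), reverse=True),
            "signed_communities": {
                "per_community": self.signed_communities.to_rows(),
                "inter_pos": self.signed_communities.inter_pos,
                "inter_neg": self.signed_communities.inter_neg,
                "intra_neg_pct": self.signed_communities.intra_neg_pct(),
            },
            "metrics": self.metrics.to_dict(),
            "metrics_std": self.metrics_std,
            "ensemble_mean_similarity": self.ensemble_mean_similarity,
            "size_fit": dataclasses.asdict(self.size_fit) if self.size_fit else None,
            "negative_hubs": self.hubs.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labeled with stage
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("read")
def _load(cfg: AnalysisConfig) -> DirectedSignedNetwork:
    if cfg.input_path is None:
        raise ValueError("config has no input path")
    if cfg.input_format == "adjacency":
        return read_signed_adjacency(cfg.input_path)
    if cfg.input_format == "edgelist":
        return read_signed_edgelist(cfg.input_path)
    raise ValueError(f"unknown input format {cfg.input_format!r}")


def run_pipeline(
    cfg: AnalysisConfig, network: DirectedSignedNetwork | None = None
) -> AnalysisReport:
    """Run the full analysis; `network` bypasses the read stage when given."""
    directed = network if network is not None else _load(cfg)

    census = classify_relationships(directed)
    try:
        dpos = dunbar_ratio(census, +1)
    except UndefinedMetricError:
        dpos = None
    try:
        dneg = dunbar_ratio(census, -1)
    except UndefinedMetricError:
        dneg = None

    completion_report = None
    if cfg.completion:
        directed, completion_report = complete_negative_links(
            directed,
            include_positive_reverse=(cfg.completion_policy == "permissive"),
        )

    recip, drop = reciprocal_projection(directed)
    summary = degree_summary(recip, truncate=cfg.truncate)
    positive = subnetwork_by_sign(recip, 1)

    if cfg.method == "newman":
        partition = newman_partition(positive)
        ens = [partition]
    elif cfg.method == "louvain":
        rng = np.random.default_rng(cfg.seed)
        seeds = rng.integers(0, 2**31 - 1, size=max(1, cfg.runs))
        ens = [louvain_partition(positive, gamma=cfg.gamma, seed=int(s)) for s in seeds]
        partition = ens[0]
    else:
        raise PipelineError("detection", f"unknown method {cfg.method!r}")

    reports = [
        metrics_report(
            recip,
            p,
            stability_thresholds=cfg.stability_thresholds,
            min_community_size=cfg.min_community_size,
        )
        for p in ens
    ]
    metrics = reports[0]
    metrics_std = None
    mean_sim = None
    if len(ens) > 1:
        fields = ["q_pos", "q_neg", "q_signed", "frustration_norm", "csb", "ppc_pct"]
        means, stds = {}, {}
        for f in fields:
            vals = [getattr(r, f) for r in reports if getattr(r, f) is not None]
            means[f] = float(np.mean(vals)) if vals else None
            stds[f] = float(np.std(vals)) if vals else None
        ens_metrics = MetricsReport(
            q_pos=means["q_pos"],
            q_neg=means["q_neg"],
            q_signed=means["q_signed"],
            frustration_norm=means["frustration_norm"],
            csb=means["csb"],
            ppc_pct=means["ppc_pct"],
            stability_class=(
                None
                if means["ppc_pct"] is None
                else _classify(means["ppc_pct"], cfg.stability_thresholds)
            ),
            q_neg_defined=reports[0].q_neg_defined,
            ppc_defined=all(r.ppc_defined for r in reports),
        )
        metrics = ens_metrics
        metrics_std = stds
        sims = [
            partition_similarity(ens[a], ens[b])
            for a in range(min(len(ens), 20))
            for b in range(a + 1, min(len(ens), 20))
        ]
        mean_sim = float(np.mean(sims)) if sims else None

    scs = build_signed_communities(recip, partition)
    sizes = [s for s in partition.sizes() if s >= cfg.min_community_size]
    size_fit = fit_exponential_ccdf(sizes) if len(sizes) >= 5 else None
    hubs = negative_hubs(scs, cfg.hub_threshold)

    report = AnalysisReport(
        config=cfg.to_dict(),
        version=__version__,
        degree_summary=summary,
        census=census,
        dunbar_pos=dpos,
        dunbar_neg=dneg,
        completion=completion_report,
        drop_report=drop.to_dict(),
        partition=partition,
        signed_communities=scs,
        metrics=metrics,
        metrics_std=metrics_std,
        ensemble_mean_similarity=mean_sim,
        size_fit=size_fit,
        hubs=hubs,
    )
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        with open(out / "partition.csv", "w") as fh:
            fh.write("node,community\n")
            for v, c in partition.assignment.items():
                fh.write(f"{v},{c}\n")
    return report


def _classify(ppc_pct: float, thresholds: tuple[float, float]) -> str:
    from .metrics import classify_stability

    return classify_stability(ppc_pct, thresholds)
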