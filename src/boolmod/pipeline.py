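"""Modularity vs. robustness simulation study, at desk scale.

For each module count ``m``, random nested-canalizing networks with fixed
size and in-degree are generated; for each network the dynamical complexity
(number of attractors discovered from random initial states) and the
phenotypical robustness (fraction of one-bit perturbations of those same
states that preserve the attractor) are estimated.  Mean robustness as a
function of discovered attractor count x is summarized by the two-parameter
decay ``y = alpha + (1 - alpha) * exp(-k (x - 1))``, which passes through
``y(1) = 1`` by construction.

The default configuration keeps the generative conditions of the study of
record (in-degree 3, nested canalizing rules, equal-size strongly connected
modules, 500 sampled initial states per network) but shrinks the network
size and replicate count to desk scale; the qualitative orderings —
complexity increasing with m, robustness at fixed complexity increasing
with m — are preserved at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .generate import GeneratorConfig, generate_modular_network
from .robustness import sampled_analysis

__all__ = [
    "ExperimentConfig",
    "FitResult",
    "run_experiment",
    "fit_robustness_decay",
    "summarize",
    "decay_curve",
]


@dataclass(frozen=True)
class ExperimentConfig:
    N: int = 16
    in_degree: int = 3
    module_counts: tuple[int, ...] = (1, 2, 4)
    networks_per_condition: int = 200
    samples_per_network: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.module_counts:
            GeneratorConfig(self.N, m, self.in_degree)  # validates divisibility
        if self.networks_per_condition < 1:
            raise ValueError("networks_per_condition must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Fitted decay of mean robustness with attractor count."""

    alpha: float
    k: float
    means: pd.DataFrame = field(compare=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return decay_curve(np.asarray(x, dtype=float), self.alpha, self.k)


def decay_curve(x: np.ndarray, alpha: float, k: float) -> np.ndarray:
    """``y = alpha + (1 - alpha) exp(-k (x - 1))``; y(1) = 1 for any (alpha, k)."""
    return alpha + (1.0 - alpha) * np.exp(-k * (x - 1.0))


def run_experiment(cfg: ExperimentConfig, out_csv: str | None = None) -> pd.DataFrame:
    """One record per generated network: (m, replicate, complexity, robustness).

    Each network gets an independent child seed spawned from ``cfg.seed``, so
    reruns are bit-identical and individual networks can be regenerated from
    their recorded seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.module_counts) * cfg.networks_per_condition)
    rows = []
    idx = 0
    for m in cfg.module_counts:
        for rep in range(cfg.networks_per_condition):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            net, _ = generate_modular_network(
                GeneratorConfig(cfg.N, m, cfg.in_degree), rng
            )
            report, aset = sampled_analysis(net, cfg.samples_per_network, rng=rng)
            rows.append(
                {
                    "m": m,
                    "replicate": rep,
                    "seed_key": int(child.spawn_key[-1]),
                    "n_attractors_found": len(aset),
                    "r_estimate": report.r_estimate,
                }
            )
    records = pd.DataFrame(rows)
    if out_csv is not None:
        records.to_csv(out_csv, index=False)
    return records


def fit_robustness_decay(
    records: pd.DataFrame,
    x_range: tuple[int, int] = (1, 19),
    min_bin: int = 5,
) -> FitResult:
    """Least-squares (alpha, k) fit to mean robustness per attractor count.

    Bins with fewer than ``min_bin`` networks are excluded (sparse bins
    destabilize the fit).  Raises when fewer than two usable bins remain.
    """
    lo, hi = x_range
    sub = records[
        (records["n_attractors_found"] >= lo) & (records["n_attractors_found"] <= hi)
    ]
    grouped = (
        sub.groupby("n_attractors_found")["r_estimate"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_r", "count": "n_networks"})
    )
    usable = grouped[grouped["n_networks"] >= min_bin]
    if len(usable) < 2:
        raise ValueError("need at least two populated attractor-count bins")
    x = usable["n_attractors_found"].to_numpy(dtype=float)
    y = usable["mean_r"].to_numpy(dtype=float)
    (alpha, k), _ = curve_fit(
        decay_curve, x, y, p0=(0.5, 0.5), bounds=([0.0, 0.0], [1.0, np.inf]),
        maxfev=10_000,
    )
    return FitResult(float(alpha), float(k), grouped)


def summarize(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Stratified tables: complexity ECDF by m, mean robustness by (m, count)."""
    if records.empty:
        return {
            "ecdf": pd.DataFrame(columns=["m", "n_attractors_found", "ecdf"]),
            "mean_robustness": pd.DataFrame(
                columns=["m", "n_attractors_found", "mean_r", "n_networks"]
            ),
        }
    ecdf_rows = []
    for m, grp in records.groupby("m"):
        counts = np.sort(grp["n_attractors_found"].to_numpy())
        xs = np.unique(counts)
        for x in xs:
            ecdf_rows.append(
                {"m": m, "n_attractors_found": int(x),
                 "ecdf": float(np.mean(counts <= x))}
            )
    mean_r = (
        records.groupby(["m", "n_attractors_found"])["r_estimate"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_r", "count": "n_networks"})
    )
    return {"ecdf": pd.DataFrame(ecdf_rows), "mean_robustness": mean_r}


def plot_summary(records: pd.DataFrame, out_prefix: str) -> list[str]:
    """Optional ECDF / decay plots (PNG); returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = summarize(records)
    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for m, grp in tables["ecdf"].groupby("m"):
        ax.step(grp["n_attractors_found"], grp["ecdf"], where="post", label=f"m={m}")
    ax.set_xlabel("number of attractors found")
    ax.set_ylabel("cumulative fraction of networks")
    ax.legend()
    p = f"{out_prefix}_ecdf.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    for m, grp in tables["mean_robustness"].groupby("m"):
        ax.plot(grp["n_attractors_found"], grp["mean_r"], "o-", label=f"m={m}")
    ax.set_xlabel("number of attractors found")
    ax.set_ylabel("mean phenotypical robustness")
    ax.legend()
    p = f"{out_prefix}_robustness.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
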