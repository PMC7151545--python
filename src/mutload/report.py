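"""Reproducibility report: regenerate every headline artifact in one run.

``run_report`` evaluates the closed-form worked numbers (fitness variance
and standard deviation, idealized and fittest-likely maxima, z-scores,
wild-type-free log probabilities, the historical comparison values, the
central-range probability), the fittest-likely reference grid, and the
simulated fitness histograms, writing them as TSV/JSON/PNG to an output
directory.  Re-running with the same config and seed reproduces every
file byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from mutload.parameters import (
    LoadParameters,
    ParameterError,
    Scheme,
    make_parameters,
)
from mutload.equilibrium import wildtype_free_log_probability
from mutload.distribution import (
    lognormal_parameters,
    lognormal_range_probability,
    variance_asymptotic,
    variance_exact,
)
from mutload.extremes import (
    TABLE1_F_VALUES,
    TABLE1_S_VALUES,
    fittest_likely,
    format_table1,
    idealized_max,
    idealized_z_score,
    table1_grid,
)
from mutload.simulation import figure1_histograms

__all__ = ["ReportBundle", "run_report", "worked_numbers"]

logger = logging.getLogger(__name__)

#: Genome size used in the comparison with Graur's haploid-site fertility
#: argument (his slightly smaller genome estimate).
GRAUR_G = 6.114e9


@dataclass(frozen=True)
class ReportBundle:
    """Paths and values produced by :func:`run_report`."""

    out_dir: Path
    params: LoadParameters
    worked: dict[str, Any]
    table1: pd.DataFrame
    histograms: pd.DataFrame
    seed: int


def worked_numbers(params: LoadParameters) -> dict[str, Any]:
    """Closed-form headline quantities for the given parameter set.

    Includes, at the set's own ``f`` and ``s``: the variance and sd of
    whole-genome fitness, the lognormal parameters, the idealized and
    fittest-likely maxima under both additive and recessive schemes with
    z-scores and wild-type-free log probabilities; plus two fixed
    comparisons — the idealized ratios at ``f = 0.10`` and ``f = 0.20``
    with the smaller genome used in the fertility-limit argument, and the
    probability that fitness falls in (0.5, 2) for a per-genome
    deleterious rate ``nu = 10`` with ``s = 0.01``.
    """
    add = params.with_(scheme=Scheme.ADDITIVE)
    rec = params.with_(scheme=Scheme.RECESSIVE)
    dist = lognormal_parameters(add)
    out: dict[str, Any] = {
        "nus": add.nus,
        "variance_exact": variance_exact(add),
        "variance_asymptotic": variance_asymptotic(add),
        "sd": dist.sd_W,
        "mu_log": dist.mu_log,
        "sigma2_log": dist.sigma2_log,
    }
    for name, p in (("additive", add), ("recessive", rec)):
        ext = fittest_likely(p, c=5.0)
        out[name] = {
            "w_max_ideal_exact": idealized_max(p).exact,
            "w_max_ideal_asymptotic": idealized_max(p).asymptotic,
            "w_max_likely": ext.w_max_likely,
            "w_max_likely_exact": ext.w_max_likely_exact,
            "z_score_ideal": idealized_z_score(p),
            "log_prob_wildtype_free": wildtype_free_log_probability(p),
        }
    graur = {}
    for f_cmp in (0.10, 0.20):
        p_cmp = add.with_(f=f_cmp, g=GRAUR_G)
        graur[f"f_{f_cmp:g}"] = idealized_max(p_cmp).asymptotic
    out["graur_comparison"] = graur
    # Central-range probability for nu = 10 per genome, s = 0.01:
    # log W ~ Normal(-0.05, 0.1).
    nu, s_cmp = 10.0, 0.01
    out["lesecque_range_probability"] = lognormal_range_probability(
        -0.5 * nu * s_cmp, nu * s_cmp, 0.5, 2.0
    )
    for key, val in out.items():
        logger.info("worked number %s = %s", key, val)
    return out


def _parse_config(config: Mapping[str, Any]) -> tuple[LoadParameters, dict[str, Any]]:
    param_keys = {"g", "f", "v", "p", "u", "s", "h", "N", "scheme"}
    params = make_parameters(**{k: v for k, v in config.items() if k in param_keys})
    extras = {
        "f_values": tuple(config.get("f_values", TABLE1_F_VALUES)),
        "s_values": tuple(config.get("s_values", TABLE1_S_VALUES)),
        "M": int(config.get("M", 100_000)),
        "seed": int(config.get("seed", 0)),
    }
    if len(extras["s_values"]) == 0:
        raise ParameterError("s_values: grid must be non-empty")
    if len(extras["f_values"]) == 0:
        raise ParameterError("f_values: grid must be non-empty")
    return params, extras


def run_report(
    config: Mapping[str, Any] | None, out_dir: str | Path, plot: bool = True
) -> ReportBundle:
    """Generate the full report bundle under ``out_dir``.

    ``config`` holds the parameter keys (``g, f, v, p, u, s, h, N,
    scheme``) plus ``f_values``, ``s_values``, ``M`` and ``seed``;
    omitted keys take the canonical defaults.
    """
    params, extras = _parse_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    worked = worked_numbers(params)
    grid = table1_grid(extras["f_values"], extras["s_values"], params=params)
    hist = figure1_histograms(
        params.with_(f=0.25) if "f" not in (config or {}) else params,
        s_values=extras["s_values"],
        M=extras["M"],
        seed=extras["seed"],
    )

    (out / "parameters.json").write_text(
        json.dumps(params.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    format_table1(grid).to_csv(out / "table1.tsv", sep="\t")
    hist.to_csv(out / "figure1.tsv", sep="\t", index=False)
    from mutload import __version__ as version

    meta = {
        "version": version,
        "seed": extras["seed"],
        "M": extras["M"],
        "f_values": list(extras["f_values"]),
        "s_values": list(extras["s_values"]),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    (out / "worked_numbers.json").write_text(
        json.dumps(worked, indent=2, sort_keys=True) + "\n"
    )
    if plot:
        _plot_histograms(hist, out / "figure1.png")
    logger.info("report written to %s", out)
    return ReportBundle(
        out_dir=out,
        params=params,
        worked=worked,
        table1=grid,
        histograms=hist,
        seed=extras["seed"],
    )


def _plot_histograms(hist: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s_values = sorted(hist["s"].unique())
    fig, axes = plt.subplots(len(s_values), 1, figsize=(6, 2.5 * len(s_values)))
    if len(s_values) == 1:
        axes = [axes]
    for ax, s in zip(axes, s_values):
        sub = hist[hist["s"] == s]
        width = sub["bin_right"].iloc[0] - sub["bin_left"].iloc[0]
        ax.bar(sub["bin_left"], sub["frequency"], width=width, align="edge")
        marker = sub["w_max_likely"].iloc[0]
        ax.axvline(marker, linestyle="--", color="k")
        ax.set_xlim(0, max(3.0, 1.2 * marker))
        ax.set_ylabel("frequency")
        ax.set_title(f"s = {s:g} (fittest likely at w = {marker:.2f})")
    axes[-1].set_xlabel("whole-genome fitness W")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
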