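"""Figure-level reproduction pipeline.

Each named figure bundles a model, its printed parameter set, an input
specification and analysis settings into a default config; ``run_figure``
executes it deterministically (seeded) and writes CSV/JSON artifacts (and
optionally a matplotlib plot).  ``verify`` runs a fast self-check battery
and writes a machine-readable pass/fail report.

Grids and durations marked "reduced" are scaled down from
publication-quality resolution so every figure runs on a laptop in minutes;
the qualitative structure (locking bands, jump directions, non-monotonic
regions) is unaffected.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .analysis import ResponseCurve, detect_nonmonotonic, estimate_rate
from .lif import response_curve_lif, simulate_tm_lif
from .neurons import FHN_FIG3, HH_FIG4, response_curve_ode, simulate_fhn, simulate_hh
from .theory import FIG2A, FIG2B, FIG5C, critical_frequencies, theory_curve
from .trains import GammaInputSpec, SweepSpec, generate_gamma, generate_sweep

__all__ = ["FIGURES", "run_figure", "verify"]

# Default configs.  Model parameters are the printed sets; grid ranges,
# durations and the sweep schedule are package design choices (the sources
# print only "ten-fold increase" for the sweep and the axes ranges).
FIGURES: Dict[str, dict] = {
    "fig1": {
        "kind": "sweep",
        "lif": {"params": FIG2A, "rate_start": 0.05, "rate_end": 0.5,
                "duration": 4000.0},
        "fhn": {"params": FHN_FIG3, "rate_start": 0.008, "rate_end": 0.08,
                "duration": 6000.0},
        "hh": {"params": HH_FIG4, "rate_start": 0.025, "rate_end": 0.25,
               "duration": 3000.0},
    },
    "fig2a": {"kind": "theory", "params": FIG2A, "rate_min": 0.01,
              "rate_max": 3.0, "points": 500},
    "fig2b": {"kind": "theory", "params": FIG2B, "rate_min": 0.01,
              "rate_max": 6.0, "points": 500},
    "fig3": {"kind": "ode", "model": "fhn", "params": FHN_FIG3,
             "rate_min": 0.005, "rate_max": 0.08, "points": 25,  # reduced
             "duration": 4000.0, "rtol": 1e-6, "atol": 1e-8},
    "fig4": {"kind": "ode", "model": "hh", "params": HH_FIG4,
             "rate_min": 0.10, "rate_max": 0.25, "points": 25,  # reduced
             "duration": 2200.0},
    "fig5a": {"kind": "gamma", "params": FIG2A, "alpha": 100.0,
              "rate_min": 0.1, "rate_max": 3.0, "points": 25,
              "n_events": 4000},
    "fig5b": {"kind": "gamma", "params": FIG2B, "alpha": 100.0,
              "rate_min": 0.5, "rate_max": 6.0, "points": 25,
              "n_events": 4000},
    "fig5c": {"kind": "gamma", "params": FIG5C, "alpha": 100.0,
              "rate_min": 0.1, "rate_max": 8.0, "points": 25,
              "n_events": 4000},
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(repr(sorted(config.items())).encode()).hexdigest()[:12]


def _log(outdir: Path, name: str, config: dict, seed: int) -> None:
    record = {
        "figure": name,
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": {k: str(v) for k, v in config.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / f"{name}_run.json").write_text(json.dumps(record, indent=2))


def run_figure(
    name: str,
    outdir: str | Path = "results",
    seed: int = 0,
    overrides: Optional[dict] = None,
    plot: bool = False,
) -> List[Path]:
    """Reproduce one named figure; returns the paths written.

    Same config and seed produce byte-identical CSV outputs.
    """
    if name not in FIGURES:
        raise KeyError(f"unknown figure {name!r}; choose from {sorted(FIGURES)}")
    config = dict(FIGURES[name])
    if overrides:
        unknown = set(overrides) - set(config)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        config.update(overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    if config["kind"] == "theory":
        grid = np.linspace(config["rate_min"], config["rate_max"], config["points"])
        df = theory_curve(config["params"], grid)
        path = outdir / f"{name}_curve.csv"
        df.to_csv(path, index=False)
        written.append(path)
        jumps = critical_frequencies(
            config["params"], (config["rate_min"], config["rate_max"]),
            resolution=4 * config["points"])
        jpath = outdir / f"{name}_jumps.json"
        jpath.write_text(json.dumps(
            [{"rate_in": r, "direction": d} for r, d in jumps], indent=2))
        written.append(jpath)

    elif config["kind"] == "ode":
        grid = np.linspace(config["rate_min"], config["rate_max"], config["points"])
        kwargs = {k: config[k] for k in ("rtol", "atol") if k in config}
        curve = response_curve_ode(config["model"], config["params"], grid,
                                   duration=config["duration"], **kwargs)
        path = outdir / f"{name}_curve.csv"
        curve.to_csv(path)
        written.append(path)
        spath = outdir / f"{name}_summary.json"
        spath.write_text(json.dumps({
            "decreasing_regions": detect_nonmonotonic(curve),
            "labels": [str(l) for l in curve.labels],
        }, indent=2))
        written.append(spath)

    elif config["kind"] == "gamma":
        grid = np.linspace(config["rate_min"], config["rate_max"], config["points"])
        curve = response_curve_lif(config["params"], grid,
                                   alpha=config["alpha"],
                                   n_events=config["n_events"], seed=seed)
        path = outdir / f"{name}_curve.csv"
        curve.to_csv(path)
        written.append(path)
        # interval histogram of the middle grid point (distribution inset)
        mid_rate = float(grid[len(grid) // 2])
        spec = GammaInputSpec(config["alpha"], mid_rate, config["n_events"],
                              seed=seed + len(grid) // 2)
        intervals = generate_gamma(spec).intervals()
        hist, edges = np.histogram(intervals, bins=50, density=True)
        hpath = outdir / f"{name}_interval_hist.csv"
        np.savetxt(hpath, np.column_stack([0.5 * (edges[:-1] + edges[1:]), hist]),
                   delimiter=",", header="interval,density", comments="")
        written.append(hpath)

    elif config["kind"] == "sweep":
        for model in ("lif", "fhn", "hh"):
            sub = config[model]
            spec = SweepSpec(sub["rate_start"], sub["rate_end"], sub["duration"],
                             unit="ms" if model == "hh" else "dimensionless")
            train = generate_sweep(spec)
            if model == "lif":
                out = simulate_tm_lif(sub["params"], train).output_train
            elif model == "fhn":
                out = simulate_fhn(sub["params"], train, rtol=1e-6,
                                   atol=1e-8).output_train
            else:
                out = simulate_hh(sub["params"], train).output_train
            for tag, tr in (("input", train), ("output", out)):
                path = outdir / f"{name}_{model}_{tag}.txt"
                tr.to_text(path)
                written.append(path)

    if plot:
        written.append(_plot_figure(name, config, outdir))
    _log(outdir, name, config, seed)
    written.append(outdir / f"{name}_run.json")
    return written


def _plot_figure(name: str, config: dict, outdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    fig, ax = plt.subplots(figsize=(5, 3.2))
    csv = outdir / f"{name}_curve.csv"
    if csv.exists():
        df = pd.read_csv(csv)
        ax.plot(df["rate_in"], df["rate_out"], ".-", ms=3)
        ax.set_xlabel("input rate")
        ax.set_ylabel("output rate")
    ax.set_title(name)
    path = outdir / f"{name}.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def verify(out: str | Path = "results/verify.json", seed: int = 0) -> dict:
    """Fast release-gate self-checks; writes and returns a pass/fail table.

    Checks (seconds of compute): closed-form theory equals the event-driven
    simulator on a coarse rate grid for both reference parameter sets; jump
    directions match the expected structure; the rate estimator is exact on
    periodic trains; gamma intervals at alpha=100 have relative std 0.1
    within three Monte-Carlo standard errors.
    """
    from .lif import stationary_rate
    from .theory import closed_form_rate
    from .trains import generate_periodic

    report = {}

    for tag, params, hi in (("fig2a", FIG2A, 3.0), ("fig2b", FIG2B, 6.0)):
        grid = np.linspace(0.1, hi, 60)
        ok = True
        worst = 0.0
        for r in grid:
            est, _ = stationary_rate(params, float(r))
            th = closed_form_rate(params, float(r))
            bound = est.error if est.error else 1e-12
            worst = max(worst, abs(est.rate - th))
            ok = ok and abs(est.rate - th) <= bound
        report[f"theory_vs_sim_{tag}"] = {"pass": bool(ok), "max_abs_dev": worst}

    dirs_a = {d for _, d in critical_frequencies(FIG2A, (0.05, 3.0), 1000)}
    dirs_b = {d for _, d in critical_frequencies(FIG2B, (0.05, 6.0), 1000)}
    report["jumps_fig2a_all_downward"] = {"pass": dirs_a == {"downward"}}
    report["jumps_fig2b_both_directions"] = {
        "pass": {"upward", "downward"} <= dirs_b}

    train = generate_periodic(0.73, 100)
    est = estimate_rate(train)
    report["estimator_exact_on_periodic"] = {
        "pass": bool(abs(est.rate - 1 / 0.73) < 1e-12 * est.rate)}

    n = 100_000
    iv = generate_gamma(GammaInputSpec(100.0, 1.0, n + 1, seed=seed)).intervals()
    rel_std = float(iv.std(ddof=1) / iv.mean())
    mc_se = 0.1 / np.sqrt(2 * (n - 1))  # se of a std estimate, normal approx
    report["gamma_rel_std_alpha100"] = {
        "pass": bool(abs(rel_std - 0.1) < 3 * mc_se), "value": rel_std}

    report["all_pass"] = all(v["pass"] for v in report.values())
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2))
    return report
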