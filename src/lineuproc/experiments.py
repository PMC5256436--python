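"""Figure-level experiment orchestration.

Each named experiment regenerates one of the package's canonical result
bundles from scratch — simulated ROC families, pAUC bars with bootstrap
confidence intervals, diagnosticity-vs-bias tables, Bayesian posterior
curves, decision-rule comparisons, and the sequential/simultaneous
comparison — and writes them as CSV tables plus a JSON summary echoing the
full configuration and seed.  CSV tables are the canonical output surface;
plots are optional conveniences and are never read back for numbers.

Experiments:

* ``fig1`` — ROC curves for five tasks (showup, lineups of size 2/3/6 on
  common random numbers, and 2AFC) at one d'.
* ``fig2`` — pAUC with bootstrap 95% CIs for showup and six-person lineup
  across d' levels and both F_max values.
* ``fig3`` — diagnosticity along fixed-AUC ROCs, vs F and vs bias c.
* ``fig4`` — posterior-of-guilt / information-gain curves for two d' levels
  at two criterion offsets.
* ``fig5`` — absolute vs relative-reject vs relative-guess rules for the
  six-person simultaneous lineup on one shared trial pool.
* ``fig6`` — simultaneous (absolute) vs sequential (first-ID and any-ID)
  lineups on one shared trial pool, including the non-monotone first-ID
  branch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import information_gain_curve
from .evidence import EvidenceModel, TrialPool, as_generator
from .procedures import (
    DEFAULT_DELTA,
    DecisionRule,
    default_sweep,
    run_2afc,
    run_sequential,
    run_showup,
    run_simultaneous,
    shared_size_pools,
)
from .roc import bootstrap_pauc, diagnosticity_bias_curves

__all__ = ["ExperimentConfig", "replicate", "EXPERIMENTS"]

log = logging.getLogger("lineuproc")

#: Default seed used when none is supplied; recorded in every output bundle.
DEFAULT_SEED = 1234


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run; every field has a default
    anchored to the standard study conditions (d' = 1.5, equal variance,
    10,000 trials per trial type, 2000 bootstrap replicates, F_max 0.10 and
    0.16, delta = 0.15, lineup sizes 1/2/3/6)."""

    experiment: str = "custom"
    d_prime: float = 1.5
    sigma_guilty: float = 1.0
    d_prime_levels: tuple = (1.0, 1.5, 2.0)
    bayes_d_primes: tuple = (1.0, 1.5)
    lineup_sizes: tuple = (1, 2, 3, 6)
    lineup_size: int = 6
    n_trials: int = 10_000
    n_boot: int = 2000
    f_max: tuple = (0.10, 0.16)
    delta: float = DEFAULT_DELTA
    offsets: tuple = (0.0, 1.0)
    base_rate_points: int = 101
    sweep_points: int = 161
    seed: int = DEFAULT_SEED
    out_dir: str | None = None

    def model(self, d_prime: float | None = None) -> EvidenceModel:
        return EvidenceModel(d_prime if d_prime is not None else self.d_prime,
                             self.sigma_guilty)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("d_prime_levels", "bayes_d_primes", "lineup_sizes",
                     "f_max", "offsets"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load a YAML or JSON config mirroring this dataclass."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def _sweep(cfg: ExperimentConfig, model: EvidenceModel) -> np.ndarray:
    return default_sweep(model, cfg.sweep_points)


def _fig1(cfg: ExperimentConfig, rng) -> dict[str, pd.DataFrame]:
    """ROC curves for showup, lineups of 2/3/6, and 2AFC at one d'."""
    model = cfg.model()
    sweep = _sweep(cfg, model)
    pools = shared_size_pools(model, cfg.lineup_sizes, cfg.n_trials,
                              cfg.n_trials, rng)
    frames = []
    for n, pool in sorted(pools.items()):
        task = "showup" if n == 1 else f"lineup{n}"
        if n == 1:
            rt = run_showup(model, sweep, rng=rng, pool=pool)
        else:
            rt = run_simultaneous(model, n, sweep, rng=rng, pool=pool)
        frame = rt.table[["criterion", "H", "F"]].copy()
        frame.insert(0, "task", task)
        frames.append(frame)
    rt = run_2afc(model, n_trials=cfg.n_trials, rng=rng)
    frame = rt.table[["criterion", "H", "F"]].copy()
    frame.insert(0, "task", "2afc")
    frames.append(frame)
    return {"roc": pd.concat(frames, ignore_index=True)}


def _fig2(cfg: ExperimentConfig, rng) -> dict[str, pd.DataFrame]:
    """pAUC with bootstrap CIs across procedures, d' levels and F_max."""
    rows = []
    for d in cfg.d_prime_levels:
        model = cfg.model(d)
        sweep = _sweep(cfg, model)
        for procedure, size in (("showup", 1), ("simultaneous", cfg.lineup_size)):
            pool = TrialPool.sample(model, size, cfg.n_trials, cfg.n_trials, rng)
            proc_key = "showup" if size == 1 else "simultaneous"
            for fmax in cfg.f_max:
                res = bootstrap_pauc(pool, fmax, procedure=proc_key,
                                     sweep=sweep, n_boot=cfg.n_boot, rng=rng)
                rows.append({"procedure": procedure, "lineup_size": size,
                             "d_prime": d, "f_max": fmax, "pauc": res.pauc,
                             "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "n_boot": res.n_boot})
                log.info("fig2 pauc procedure=%s d=%.2f f_max=%.2f pauc=%.5f",
                         procedure, d, fmax, res.pauc)
    return {"pauc": pd.DataFrame(rows)}


def _fig3(cfg: ExperimentConfig, rng) -> dict[str, pd.DataFrame]:
    return {"diagnosticity": diagnosticity_bias_curves()}


def _fig4(cfg: ExperimentConfig, rng) -> dict[str, pd.DataFrame]:
    frames = []
    grid = np.linspace(0.0, 1.0, cfg.base_rate_points)
    for d in cfg.bayes_d_primes:
        for k in cfg.offsets:
            curve = information_gain_curve(cfg.model(d), k, grid)
            frames.append(curve.to_frame())
    return {"bayes": pd.concat(frames, ignore_index=True)}


def _fig5(cfg: ExperimentConfig, rng) -> dict[str, pd.DataFrame]:
    """Three decision rules on one shared six-person trial pool."""
    model = cfg.model()
    sweep = _sweep(cfg, model)
    pool = TrialPool.sample(model, cfg.lineup_size, cfg.n_trials,
                            cfg.n_trials, rng)
    frames = []
    for kind in ("absolute", "relative_reject", "relative_guess"):
        rt = run_simultaneous(model, cfg.lineup_size, sweep,
                              rule=DecisionRule(kind, cfg.delta),
                              rng=rng, pool=pool)
        frame = rt.table[["criterion", "H", "F"]].copy()
        frame.insert(0, "rule", kind)
        frames.append(frame)
    return {"roc": pd.concat(frames, ignore_index=True)}


def _fig6(cfg: ExperimentConfig, rng) -> dict[str, pd.DataFrame]:
    """Simultaneous vs sequential procedures on one shared pool."""
    model = cfg.model()
    sweep = _sweep(cfg, model)
    pool = TrialPool.sample(model, cfg.lineup_size, cfg.n_trials,
                            cfg.n_trials, rng)
    runs = {
        "simultaneous": run_simultaneous(model, cfg.lineup_size, sweep,
                                         rng=rng, pool=pool),
        "sequential_first_id": run_sequential(model, cfg.lineup_size, sweep,
                                              variant="first_id", rng=rng,
                                              pool=pool),
        "sequential_any_id": run_sequential(model, cfg.lineup_size, sweep,
                                            variant="any_id", rng=rng,
                                            pool=pool),
    }
    frames = []
    for name, rt in runs.items():
        frame = rt.table[["criterion", "H", "F"]].copy()
        frame.insert(0, "procedure", name)
        frames.append(frame)
    return {"roc": pd.concat(frames, ignore_index=True)}


EXPERIMENTS = {"fig1": _fig1, "fig2": _fig2, "fig3": _fig3, "fig4": _fig4,
               "fig5": _fig5, "fig6": _fig6}


def _plot_bundle(name: str, tables: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if name in ("fig1", "fig5", "fig6"):
        key = {"fig1": "task", "fig5": "rule", "fig6": "procedure"}[name]
        for label, grp in tables["roc"].groupby(key):
            grp = grp.sort_values("F")
            ax.plot(grp["F"], grp["H"], label=str(label), lw=1)
        ax.set_xlabel("False alarm rate (F)")
        ax.set_ylabel("Hit rate (H)")
        ax.legend(fontsize=8)
    elif name == "fig2":
        tab = tables["pauc"]
        for i, ((proc, fmax), grp) in enumerate(tab.groupby(["procedure", "f_max"])):
            x = np.arange(len(grp)) + 0.18 * i
            ax.errorbar(x, grp["pauc"],
                        yerr=[grp["pauc"] - grp["ci_low"],
                              grp["ci_high"] - grp["pauc"]],
                        fmt="o", ms=3, label=f"{proc} Fmax={fmax}")
        ax.set_xlabel("d' level index")
        ax.set_ylabel("pAUC")
        ax.legend(fontsize=7)
    elif name == "fig3":
        tab = tables["diagnosticity"]
        for auc, grp in tab.groupby("auc"):
            ax.plot(grp["c"], grp["D"], label=f"AUC={auc}", lw=1)
        ax.set_xlabel("bias c")
        ax.set_ylabel("diagnosticity D")
        ax.set_yscale("log")
        ax.legend(fontsize=8)
    elif name == "fig4":
        tab = tables["bayes"]
        for (d, k), grp in tab.groupby(["d_prime", "offset"]):
            ax.plot(grp["base_rate"], grp["gain_id"],
                    label=f"d'={d}, k={k}", lw=1)
        ax.set_xlabel("base rate")
        ax.set_ylabel("information gain (id)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / f"{name}.png", dpi=150)
    plt.close(fig)


def replicate(config, out_dir=None, seed: int | None = None,
              n_trials: int | None = None, n_boot: int | None = None,
              make_plots: bool = False) -> dict[str, pd.DataFrame]:
    """Run one named experiment (or a full ExperimentConfig).

    ``config`` is either an experiment name (``fig1``..``fig6``) or an
    :class:`ExperimentConfig`.  Returns the result tables and, when
    ``out_dir`` is given, writes one CSV per table plus ``summary.json``
    echoing the complete configuration — enough to re-run the experiment
    without the original command line.  Identical seeds yield byte-identical
    CSVs.
    """
    if isinstance(config, str):
        if config not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {config!r}; choose from {sorted(EXPERIMENTS)}")
        cfg = ExperimentConfig(experiment=config)
    else:
        cfg = dataclasses.replace(config)
        if cfg.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {cfg.experiment!r}")
    if seed is not None:
        cfg.seed = int(seed)
    if n_trials is not None:
        cfg.n_trials = int(n_trials)
    if n_boot is not None:
        cfg.n_boot = int(n_boot)

    rng = as_generator(cfg.seed)
    t0 = time.perf_counter()
    log.info("experiment=%s seed=%d n_trials=%d start", cfg.experiment,
             cfg.seed, cfg.n_trials)
    tables = EXPERIMENTS[cfg.experiment](cfg, rng)
    log.info("experiment=%s done in %.2fs (%d tables)", cfg.experiment,
             time.perf_counter() - t0, len(tables))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, frame in tables.items():
            path = out / f"{cfg.experiment}_{name}.csv"
            frame.to_csv(path, index=False, float_format="%.12g")
            written[name] = path.name
        summary = {"experiment": cfg.experiment, "seed": cfg.seed,
                   "config": cfg.to_dict(), "tables": written}
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        if make_plots:
            _plot_bundle(cfg.experiment, tables, out)
    return tables
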