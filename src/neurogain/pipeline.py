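"""End-to-end runs and parameter sweeps.

``run_point`` composes the full pipeline at one gain setting: simulate the
network, measure EEG-timescale metrics on the source signals, generate
band-passed BOLD from the pyramidal rates, threshold the static FC against
FT surrogates, compute weighted graph metrics, and quantify FC dynamics --
repeated over seeds and averaged.  ``run_sweep`` maps these summaries over
1-D or 2-D gain grids (alpha, beta, r0, C1, mu, sigma), optionally with a
linkage rule such as beta = 0.5 alpha, with per-cell resumability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .connectome import StructuralConnectome, normalize_in_strength
from .eeg_metrics import spectral_summary
from .fcd import fcd_matrix, fcd_speed, fcd_variance, windowed_fcs
from .functional_connectivity import ft_surrogates, static_fc, threshold_fc
from .graph_metrics import graph_summary
from .hemodynamics import HemoParams, bandpass, decimate, simulate_bold
from .neural_mass import GainSet, JRParams, NoiseSpec, SimConfig, simulate_network

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunResult", "SweepResult", "run_point", "run_sweep"]

METRICS = (
    "E_w",
    "Q_w",
    "T_w",
    "PC_w",
    "R_bar",
    "snr_db",
    "omega_hz",
    "var_fcd",
    "d_typ",
)


@dataclass
class AnalysisConfig:
    """Settings of the analysis stages downstream of the simulation."""

    bold_fs: float = 2.0  # BOLD sampling after filtering (Hz)
    band: tuple[float, float] = (0.01, 0.1)
    n_surrogates: int = 500
    p_value: float = 0.05
    correction: str = "bh_fdr"
    louvain_runs: int = 200
    resolution: float = 1.0
    win_len: float = 100.0
    win_step: float = 2.0
    tau: float = 100.0
    bold_input: str = "pyramidal"  # or "summed" (all three populations)


@dataclass
class RunResult:
    """Seed-averaged pipeline summary at one parameter point."""

    gains: GainSet
    seeds: list[int]
    per_seed: dict[str, list[float]]
    mean: dict[str, float]
    overrides: dict = field(default_factory=dict)


@dataclass
class SweepResult:
    """Metric maps over a 1-D or 2-D parameter grid; NaN marks failed cells."""

    axes: dict[str, np.ndarray]
    maps: dict[str, np.ndarray]
    errors: dict[tuple, str] = field(default_factory=dict)


_PARAM_FIELDS = {f.name for f in fields(JRParams)}
_NOISE_FIELDS = {f.name for f in fields(NoiseSpec)} - {"seed"}
_GAIN_FIELDS = {f.name for f in fields(GainSet)}


def _apply_overrides(
    params: JRParams, noise: NoiseSpec, gains: GainSet, overrides: Mapping[str, float]
) -> tuple[JRParams, NoiseSpec, GainSet]:
    """Return copies with named parameters replaced (C1, mu, sigma, alpha, ...)."""
    pk = {k: v for k, v in overrides.items() if k in _PARAM_FIELDS}
    nk = {k: v for k, v in overrides.items() if k in _NOISE_FIELDS}
    gk = {k: v for k, v in overrides.items() if k in _GAIN_FIELDS}
    unknown = set(overrides) - set(pk) - set(nk) - set(gk)
    if unknown:
        raise ValueError(f"unknown override parameter(s): {sorted(unknown)}")
    if pk:
        params = replace(params, **pk)
    if nk:
        noise = replace(noise, **nk)
    if gk:
        gains = replace(gains, **gk)
    return params, noise, gains


def _seed_for(master: int | None, *key: int) -> int:
    """Deterministic 31-bit substream seed from a master seed and index tuple."""
    if master is None:
        master = 0
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_point(
    sc: StructuralConnectome,
    gains: GainSet,
    overrides: Mapping[str, float] | None = None,
    cfg: SimConfig | None = None,
    params: JRParams | None = None,
    noise: NoiseSpec | None = None,
    hemo: HemoParams | None = None,
    analysis: AnalysisConfig | None = None,
    seeds: Sequence[int] | None = None,
) -> RunResult:
    """Full pipeline at one gain setting, repeated per seed and averaged.

    Stages: simulate -> EEG metrics on nu -> pyramidal rates -> hemodynamic
    model -> Bessel band-pass + decimation -> static FC -> FT-surrogate
    threshold -> graph metrics; windowed FCs -> FCD variance and speed.
    """
    cfg = cfg or SimConfig()
    params = params or JRParams()
    noise = noise or NoiseSpec()
    hemo = hemo or HemoParams()
    analysis = analysis or AnalysisConfig()
    params, noise, gains = _apply_overrides(params, noise, gains, overrides or {})
    if not sc.normalized:
        sc = normalize_in_strength(sc)
    if seeds is None:
        seeds = list(cfg.seeds)

    per_seed: dict[str, list[float]] = {m: [] for m in METRICS}
    record_extra = analysis.bold_input == "summed"
    # record the transient too: it warms up the hemodynamic model so the
    # shared onset response does not leak into the BOLD correlations
    cfg_full = replace(cfg, transient=0.0)
    t_trans = int(round(cfg.transient / cfg.dt))
    for seed in seeds:
        traj = simulate_network(
            sc, params, gains, noise, cfg_full, seed=seed,
            record_population_rates=record_extra,
        )
        spec = spectral_summary(traj.eeg[:, t_trans:], traj.fs)

        drive = traj.rates
        if record_extra:
            drive = traj.rates + traj.rates_exc + traj.rates_inh
        bold = simulate_bold(drive, hemo, dt=1.0 / traj.fs)
        # drop the warm-up BEFORE filtering: the onset step would otherwise
        # leak ~100 s forward through the non-causal band-pass
        bold = replace(bold, data=bold.data[:, t_trans:])
        bold = bandpass(bold, *analysis.band)
        bold = decimate(bold, analysis.bold_fs)

        fc = static_fc(bold)
        ens = ft_surrogates(bold, n=analysis.n_surrogates, seed=_seed_for(seed, 1))
        tfc = threshold_fc(fc, ens, p=analysis.p_value, correction=analysis.correction)
        gs = graph_summary(
            tfc, runs=analysis.louvain_runs, resolution=analysis.resolution,
            seed=_seed_for(seed, 2),
        )

        stream, starts = windowed_fcs(bold, analysis.win_len, analysis.win_step)
        fcd = fcd_matrix(stream, starts, analysis.win_len, analysis.win_step)
        var_fcd = fcd_variance(fcd, analysis.tau)
        d_typ = fcd_speed(fcd, analysis.tau)

        for key, val in (
            ("E_w", gs.E_w), ("Q_w", gs.Q_w), ("T_w", gs.T_w), ("PC_w", gs.PC_w_mean),
            ("R_bar", spec.R_bar), ("snr_db", spec.snr_db_mean),
            ("omega_hz", spec.omega_mean), ("var_fcd", var_fcd), ("d_typ", d_typ),
        ):
            per_seed[key].append(float(val))

    mean = {m: float(np.mean(v)) for m, v in per_seed.items()}
    return RunResult(
        gains=gains, seeds=list(seeds), per_seed=per_seed, mean=mean,
        overrides=dict(overrides or {}),
    )


def run_sweep(
    sc: StructuralConnectome,
    axes: Mapping[str, Sequence[float]],
    cfg: SimConfig | None = None,
    params: JRParams | None = None,
    noise: NoiseSpec | None = None,
    hemo: HemoParams | None = None,
    analysis: AnalysisConfig | None = None,
    gains: GainSet | None = None,
    linkage: Mapping[str, float] | None = None,
    master_seed: int = 0,
    n_seeds: int | None = None,
    out_dir: str | Path | None = None,
) -> SweepResult:
    """Map the pipeline summaries over a 1-D or 2-D parameter grid.

    ``axes`` maps parameter names (alpha, beta, r0, C1, mu, sigma) to
    grids.  ``linkage`` ties a second parameter to the first axis, e.g.
    ``{"beta": 0.5}`` sets beta = 0.5 * alpha at every cell.  Each cell
    gets independent, reproducible seed substreams derived from
    ``master_seed``; with ``out_dir`` finished cells are cached as JSON and
    skipped on resume.  Per-cell failures are recorded and the sweep
    continues.
    """
    if not 1 <= len(axes) <= 2:
        raise ValueError("axes must contain one or two parameters")
    cfg = cfg or SimConfig()
    gains = gains or GainSet()
    if n_seeds is None:
        n_seeds = len(cfg.seeds)

    names = list(axes)
    grids = [np.asarray(axes[k], dtype=float) for k in names]
    shape = tuple(len(g) for g in grids)
    maps = {m: np.full(shape, np.nan) for m in METRICS}
    errors: dict[tuple, str] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for idx in np.ndindex(*shape):
        cell = {names[d]: float(grids[d][idx[d]]) for d in range(len(names))}
        if linkage:
            for dep, coef in linkage.items():
                cell[dep] = coef * cell[names[0]]
        cache = out_path / ("cell_" + "_".join(f"{k}{v:.6g}" for k, v in sorted(cell.items())) + ".json") if out_path else None
        if cache is not None and cache.exists():
            cached = json.loads(cache.read_text())
            for m in METRICS:
                maps[m][idx] = cached["mean"][m]
            continue
        lin = int(np.ravel_multi_index(idx, shape))
        seeds = [_seed_for(master_seed, lin, k) for k in range(n_seeds)]
        try:
            res = run_point(
                sc, gains, overrides=cell, cfg=cfg, params=params, noise=noise,
                hemo=hemo, analysis=analysis, seeds=seeds,
            )
        except Exception as exc:  # record and continue
            logger.error("sweep cell %s failed: %s", cell, exc)
            errors[tuple(idx)] = f"{cell}: {exc}"
            continue
        for m in METRICS:
            maps[m][idx] = res.mean[m]
        if cache is not None:
            cache.write_text(json.dumps({"cell": cell, "mean": res.mean, "per_seed": res.per_seed}))

    return SweepResult(axes={k: g for k, g in zip(names, grids)}, maps=maps, errors=errors)
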