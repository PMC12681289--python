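"""Reproducible experiment driver: config in, corrected waveforms,
simulated reconstructions, metrics and report artifacts out.

A run applies exactly one correction method (none, exponential
pre-emphasis, GSTF pre-emphasis, or k-space optimization) to a benchmark
EPI sequence under a distortion model, simulates the phantom signal at the
realized k-locations, reconstructs on the nominal grid, and scores the
image against the distortion-free reconstruction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distortion import EddyModel, TransferFunction, apply_model, make_synthetic_tf
from .epi import AdcSampling, EpiSequenceSpec, build_epi_all
from .optimize import (
    HardwareLimits,
    OptimizationProblem,
    OptimizationResult,
    k_rmse,
    kspace_loss,
    optimize,
)
from .preemphasis import PreemphasisParams, TukeySpec, exp_preemphasis, fit_preemphasis, gstf_preemphasis
from .simrecon import Phantom2D, ellipse_phantom, ghost_metric, nrmse, reconstruct, simulate_signal
from .waveform import GradientWaveform, load_waveform_h5, save_waveform_h5, waveform_kspace

logger = logging.getLogger("girfopt")

METHODS = ("none", "exp_preemphasis", "gstf_preemphasis", "optimize")


@dataclass
class ExperimentConfig:
    """One correction method applied to one sequence under one model."""

    sequence: EpiSequenceSpec = field(default_factory=EpiSequenceSpec)
    model: object = field(default_factory=lambda: EddyModel(terms=[(5e-6, 50e-6)]))
    method: str = "none"
    limits: HardwareLimits = field(default_factory=HardwareLimits)
    learning_rate: float = 0.05
    lr_final: float | None = 1e-8
    n_iters: int = 5000
    w_g: float = 1e3
    w_s: float = 1e3
    tukey: TukeySpec | None = field(default_factory=TukeySpec)
    preemphasis_params: PreemphasisParams | None = None  # fitted when None
    seed: int = 0
    output_dir: Path | None = None
    quiet: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "ExperimentConfig":
        seq = EpiSequenceSpec.from_dict(raw.get("sequence", {}))
        msrc = raw.get("model", {"type": "eddy", "terms": [[5e-6, 50e-6]]})
        mtype = msrc.get("type", "eddy")
        if mtype == "eddy":
            model: object = EddyModel(terms=[tuple(t) for t in msrc.get("terms", [])])
        elif mtype == "gstf":
            p = Path(msrc["path"])
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise FileNotFoundError(f"transfer function file not found: {p}")
            model = TransferFunction.load_h5(p)
        elif mtype == "synthetic_gstf":
            model = make_synthetic_tf(
                eddy=EddyModel(terms=[tuple(t) for t in msrc.get("terms", [])]),
                delay=msrc.get("delay", 0.0),
                resonances=[tuple(r) for r in msrc.get("resonances", [])],
                cross_scale=msrc.get("cross_scale", 0.0),
                dt=seq.dt,
            )
        else:
            raise ValueError(f"unknown model type {mtype!r}")
        opt = raw.get("optimizer", {})
        tk = raw.get("tukey")
        out = raw.get("output_dir")
        return cls(
            sequence=seq,
            model=model,
            method=raw.get("method", "none"),
            limits=HardwareLimits(
                g_max=opt.get("g_max", 72.0), s_max=opt.get("s_max", 180.0)
            ),
            learning_rate=opt.get("learning_rate", 0.05),
            n_iters=opt.get("n_iters", 5000),
            w_g=opt.get("w_g", 1e3),
            w_s=opt.get("w_s", 1e3),
            tukey=TukeySpec(**tk) if tk else TukeySpec(),
            seed=raw.get("seed", 0),
            output_dir=Path(out) if out else None,
            quiet=raw.get("quiet", False),
        )


@dataclass
class ReconReport:
    """Metrics of one reconstructed experiment."""

    image: np.ndarray
    nrmse_percent: float
    ghost_metric: float
    k_rmse: float
    uncorrected_k_rmse: float
    peak_g: float
    peak_slew: float
    constraints_satisfied: bool
    method: str

    def metrics_dict(self) -> dict:
        return {
            "method": self.method,
            "nrmse_percent": float(self.nrmse_percent),
            "ghost_metric": float(self.ghost_metric),
            "k_rmse": float(self.k_rmse),
            "uncorrected_k_rmse": float(self.uncorrected_k_rmse),
            "peak_g": float(self.peak_g),
            "peak_slew": float(self.peak_slew),
            "constraints_satisfied": bool(self.constraints_satisfied),
        }


def _correct_waveform(
    cfg: ExperimentConfig, w: GradientWaveform, adc: AdcSampling
) -> tuple[GradientWaveform, OptimizationResult | None, PreemphasisParams | None]:
    if cfg.method == "none":
        return w, None, None
    if cfg.method == "exp_preemphasis":
        if not isinstance(cfg.model, EddyModel):
            raise ValueError("exp_preemphasis requires an analytic eddy model")
        params = cfg.preemphasis_params
        if params is None:
            params, _ = fit_preemphasis(w, cfg.model)
        return exp_preemphasis(w, params), None, params
    if cfg.method == "gstf_preemphasis":
        if not isinstance(cfg.model, TransferFunction):
            raise ValueError("gstf_preemphasis requires a tabulated transfer function")
        return gstf_preemphasis(w, cfg.model, cfg.tukey), None, None
    problem = OptimizationProblem(
        initial=w,
        adc=adc,
        model=cfg.model,
        limits=cfg.limits,
        w_g=cfg.w_g,
        w_s=cfg.w_s,
        learning_rate=cfg.learning_rate,
        lr_final=cfg.lr_final,
        n_iters=cfg.n_iters,
        seed=cfg.seed,
    )
    res = optimize(problem)
    if res.limit_warning and not cfg.quiet:
        logger.warning(res.limit_warning)
    return res.waveform, res, None


def run_experiment(
    cfg: ExperimentConfig, phantom: Phantom2D | None = None
) -> tuple[ReconReport, OptimizationResult | None]:
    """Execute one configured run; deterministic given config and seed."""
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)  # single seeded source (unused in math path)
    del rng
    spec = cfg.sequence
    if phantom is None:
        phantom = ellipse_phantom(spec.matrix, spec.fov)
    if abs(phantom.fov - spec.fov) > 1e-12:
        raise ValueError("phantom FOV does not match sequence FOV")

    stage = "sequence_gen"
    try:
        shots = build_epi_all(spec)
        stage = "correction"
        corrected, opt_res, fitted = [], None, None
        for w, adc in shots:
            cw, res, params = _correct_waveform(cfg, w, adc)
            corrected.append(cw)
            opt_res = opt_res or res
            fitted = fitted or params

        stage = "forward_model"
        all_samples, all_adc = [], []
        k_err_sq, k_err_sq_unc, n_k = 0.0, 0.0, 0
        for (w, adc), cw in zip(shots, corrected):
            realized = apply_model(cw, cfg.model)
            traj = waveform_kspace(realized, adc.times, axes=(0, 1))
            all_samples.append(simulate_signal(phantom, traj))
            all_adc.append(adc)
            k_err_sq += float(np.sum((traj.k - adc.nominal_k) ** 2))
            k_err_sq_unc += kspace_loss(w, adc, cfg.model)
            n_k += adc.n_samples

        stage = "reconstruction"
        img = reconstruct(np.concatenate(all_samples), spec, all_adc)
        # distortion-free reference through the identical pipeline
        ref_samples = [
            simulate_signal(phantom, waveform_kspace(w, adc.times, axes=(0, 1)))
            for w, adc in shots
        ]
        ref = reconstruct(np.concatenate(ref_samples), spec, all_adc)

        stage = "metrics"
        peak_g = max(cw.peak_amplitude() for cw in corrected)
        peak_slew = max(cw.peak_slew() for cw in corrected)
        report = ReconReport(
            image=img,
            nrmse_percent=nrmse(img, ref),
            ghost_metric=ghost_metric(img),
            k_rmse=float(np.sqrt(k_err_sq / n_k)),
            uncorrected_k_rmse=float(np.sqrt(k_err_sq_unc / n_k)),
            peak_g=peak_g,
            peak_slew=peak_slew,
            constraints_satisfied=bool(
                peak_g <= cfg.limits.g_max * 1.005 and peak_slew <= cfg.limits.s_max * 1.005
            ),
            method=cfg.method,
        )
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage '{stage}': {exc}") from exc

    if not cfg.quiet:
        logger.info("run_experiment(%s) finished in %.1f s", cfg.method, time.time() - t0)
    if cfg.output_dir is not None:
        _write_artifacts(cfg, corrected, report, opt_res, fitted)
    return report, opt_res


def _write_artifacts(cfg, corrected, report, opt_res, fitted) -> None:
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    for i, cw in enumerate(corrected):
        save_waveform_h5(out / f"waveform_shot{i}.h5", cw)
    metrics = report.metrics_dict()
    # peaks recomputed from the written files, not in-memory state
    reloaded = [load_waveform_h5(out / f"waveform_shot{i}.h5") for i in range(len(corrected))]
    metrics["peak_g"] = float(max(w.peak_amplitude() for w in reloaded))
    metrics["peak_slew"] = float(max(w.peak_slew() for w in reloaded))
    if fitted is not None:
        metrics["preemphasis_terms"] = [[float(a), float(t)] for a, t in fitted.terms]
    if opt_res is not None:
        metrics["best_iteration"] = int(opt_res.best_iteration)
        metrics["final_k_rmse"] = float(opt_res.final_k_rmse)
        hist = pd.DataFrame(
            opt_res.loss_history, columns=["total", "k_loss", "amp_penalty", "slew_penalty"]
        )
        hist.to_csv(out / "loss_history.csv", index_label="iteration")
    (out / "metrics.yaml").write_text(yaml.safe_dump(metrics, sort_keys=True))
    manifest = {"files": sorted(p.name for p in out.iterdir())}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    try:
        _write_panels(cfg, corrected, report, out)
    except Exception as exc:  # plotting must never kill a run
        logger.warning("panel rendering failed: %s", exc)


def _write_panels(cfg, corrected, report, out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = cfg.sequence
    w = corrected[0]
    from .epi import build_epi

    nom, adc = build_epi(spec, shot=0)
    realized = apply_model(w, cfg.model)
    traj_r = waveform_kspace(realized, adc.times, axes=(0, 1))

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].plot(adc.nominal_k[:, 0], adc.nominal_k[:, 1], ".", ms=2, label="nominal")
    axes[0].plot(traj_r.k[:, 0], traj_r.k[:, 1], ".", ms=2, label="realized")
    axes[0].set_xlabel("$k_x$ (1/m)")
    axes[0].set_ylabel("$k_y$ (1/m)")
    axes[0].legend(loc="upper right", fontsize=7)
    axes[0].set_title("trajectory")
    axes[1].imshow(np.abs(report.image), cmap="gray")
    axes[1].set_title(f"{cfg.method} (NRMSE {report.nrmse_percent:.3f}%)")
    axes[1].axis("off")
    t = np.arange(w.n) * w.dt * 1e3
    axes[2].plot(t, w.samples[0], lw=0.6, label="$g_x$")
    axes[2].plot(t, w.samples[1], lw=0.6, label="$g_y$")
    axes[2].set_xlabel("t (ms)")
    axes[2].set_ylabel("g (mT/m)")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "panels.png", dpi=110)
    plt.close(fig)


def compare_methods(
    cfgs: list[ExperimentConfig], phantom: Phantom2D | None = None
) -> pd.DataFrame:
    """Run several methods on the same sequence/model; one row per method."""
    cols = [
        "method",
        "nrmse_percent",
        "ghost_metric",
        "k_rmse",
        "peak_g",
        "peak_slew",
        "constraints_satisfied",
    ]
    if not cfgs:
        return pd.DataFrame(columns=cols)
    ref = cfgs[0].sequence.to_dict()
    for c in cfgs[1:]:
        if c.sequence.to_dict() != ref:
            raise ValueError("compare_methods requires all configs to share one sequence")
    rows = []
    for c in cfgs:
        report, _ = run_experiment(c, phantom=phantom)
        rows.append({k: report.metrics_dict()[k] for k in cols})
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# standing desk-scale benchmark variants


def benchmark_specs() -> dict[str, EpiSequenceSpec]:
    """The package's standing EPI benchmark variants (desk scale).

    Scaled-down analogues of the four canonical single-slice variants plus
    the tighter-timing short-TE readout: 250 mm FOV throughout, matrix 64
    (66 for R=3 so the acceleration tiles the line grid), echo spacing
    1.07 ms (0.8 ms for the short-TE variant), partial Fourier 49/64 for
    R=1 and 51/64 for R=2, and a 4-shot interleaved variant.
    """
    return {
        "R1": EpiSequenceSpec(
            matrix=64, R=1, partial_fourier=Fraction(49, 64), echo_spacing=1.07e-3
        ),
        "R2": EpiSequenceSpec(
            matrix=64, R=2, partial_fourier=Fraction(51, 64), echo_spacing=1.07e-3
        ),
        "R3": EpiSequenceSpec(matrix=66, R=3, echo_spacing=1.07e-3),
        "multishot": EpiSequenceSpec(
            matrix=64, R=1, n_shots=4, echo_spacing=1.07e-3
        ),
        "R1_shortTE": EpiSequenceSpec(
            matrix=64, R=1, partial_fourier=Fraction(49, 64), echo_spacing=0.8e-3
        ),
    }
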