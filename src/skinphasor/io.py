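"""File formats, configuration, rendering, and the pipeline runner.

Conventions: arrays are (row, col[, time]) with a top-left pixel origin
and 0-based indices; every TIFF is accompanied by a JSON sidecar holding
the metadata needed to re-derive it (never guessed on read).  Decay
stacks are multi-page TIFFs (one page per time bin, 16-bit unsigned for
noisy counts, 32-bit float for expectations); phasor and fraction fields
are multi-channel 32-bit float TIFFs; masks are 8-bit 0/255.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__ as _pkg_version
from .phasor import (
    CalibrationFactors,
    PhasorField,
    analytic_phasor,
    apply_calibration,
    compute_calibration,
    phasor_transform,
)
from .processing import (
    DEFAULT_BIN_FACTOR,
    DEFAULT_KERATIN_MIN_AREA,
    DEFAULT_KERATIN_THRESHOLD,
    DEFAULT_MIN_PHOTONS,
    PixelMask,
    bin_spatial,
    mask_large_keratin_features,
    median_filter_phasor,
    threshold_mask,
)
from .quantify import depth_trend, ratio_summary, violin_summary
from .synthetic import (
    DEFAULT_MEAN_PHOTONS,
    AcquisitionModel,
    DecayStack,
    PhantomSpec,
    make_monoexponential_stack,
    make_phantom,
)
from .unmixing import (
    ComponentSet,
    FractionField,
    bound_nadh_ratio,
    combined_fraction_map,
    unmix,
)

logger = logging.getLogger(__name__)

AXIS_NOTE = "axes (row, col, time); origin top-left; 0-based"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload.setdefault("axes", AXIS_NOTE)
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sc}; metadata is never guessed"
        )
    return json.loads(sc.read_text())


# ---------------------------------------------------------------------------
# Decay stacks
# ---------------------------------------------------------------------------


def write_decay_tiff(stack: DecayStack, path: str | Path, **extra_meta) -> Path:
    """Write a decay stack as multi-page TIFF (pages = time bins) + sidecar."""
    path = Path(path)
    data = np.moveaxis(stack.counts, 2, 0)  # (time, row, col) pages
    if np.issubdtype(stack.counts.dtype, np.integer):
        if stack.counts.max(initial=0) >= 2**16:
            raise ValueError("integer counts exceed 16-bit range")
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        **stack.acquisition.to_dict(),
        "z_um": stack.z,
        "channel": stack.channel_label,
        "dtype": str(data.dtype),
        **extra_meta,
    }
    _write_sidecar(path, meta)
    return path


def read_decay_tiff(path: str | Path) -> DecayStack:
    """Read a decay stack written by :func:`write_decay_tiff` (lossless)."""
    path = Path(path)
    meta = _read_sidecar(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != meta["n_bins"]:
        raise ValueError(
            f"TIFF has {data.shape[0]} pages but sidecar specifies "
            f"{meta['n_bins']} time bins"
        )
    acq = AcquisitionModel.from_dict(meta)
    return DecayStack(
        counts=np.moveaxis(data, 0, 2),
        acquisition=acq,
        z=meta.get("z_um"),
        channel_label=meta.get("channel", "A0"),
    )


# ---------------------------------------------------------------------------
# Phasor / fraction fields, masks, calibration
# ---------------------------------------------------------------------------


def write_phasor_tiff(
    field: PhasorField, path: str | Path, cal: CalibrationFactors | None = None
) -> Path:
    path = Path(path)
    channels = []
    names = []
    for n in field.harmonics:
        channels += [field.g[n], field.s[n]]
        names += [f"g{n}", f"s{n}"]
    channels.append(np.asarray(field.intensity, dtype=float))
    names.append("intensity")
    tifffile.imwrite(path, np.stack(channels).astype(np.float32), photometric="minisblack")
    meta = {
        "channels": names,
        "harmonics": list(field.harmonics),
        "calibrated": field.calibrated,
        **field.acquisition.to_dict(),
    }
    if cal is not None:
        meta["calibration"] = cal.to_dict()
    _write_sidecar(path, meta)
    return path


def read_phasor_tiff(path: str | Path) -> PhasorField:
    path = Path(path)
    meta = _read_sidecar(path)
    data = tifffile.imread(path).astype(float)
    names = meta["channels"]
    if data.shape[0] != len(names):
        raise ValueError(
            f"TIFF has {data.shape[0]} channels but sidecar names {len(names)}"
        )
    chan = {name: data[i] for i, name in enumerate(names)}
    harmonics = tuple(meta["harmonics"])
    return PhasorField(
        g={n: chan[f"g{n}"] for n in harmonics},
        s={n: chan[f"s{n}"] for n in harmonics},
        intensity=chan["intensity"],
        harmonics=harmonics,
        acquisition=AcquisitionModel.from_dict(meta),
        calibrated=meta["calibrated"],
    )


def write_fraction_tiff(fractions: FractionField, path: str | Path) -> Path:
    path = Path(path)
    channels = [fractions.fractions[..., i] for i in range(len(fractions.names))]
    channels.append(fractions.intensity)
    tifffile.imwrite(path, np.stack(channels).astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {
            "channels": list(fractions.names) + ["intensity"],
            "component_tau_ns": dict(zip(fractions.names, fractions.taus)),
        },
    )
    return path


def read_fraction_tiff(path: str | Path) -> FractionField:
    path = Path(path)
    meta = _read_sidecar(path)
    data = tifffile.imread(path).astype(float)
    names = tuple(meta["channels"][:-1])
    taus = tuple(meta["component_tau_ns"][n] for n in names)
    return FractionField(
        fractions=np.stack([data[i] for i in range(len(names))], axis=-1),
        intensity=data[len(names)],
        names=names,
        taus=taus,
    )


def write_mask_tiff(mask: PixelMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.where(mask.include, 255, 0).astype(np.uint8), photometric="minisblack")
    _write_sidecar(path, {"provenance": mask.provenance, "encoding": "255=include"})
    return path


def read_mask_tiff(path: str | Path) -> PixelMask:
    path = Path(path)
    meta = _read_sidecar(path)
    return PixelMask(tifffile.imread(path) > 0, provenance=meta.get("provenance", ""))


def write_calibration_json(cal: CalibrationFactors, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cal.to_dict(), indent=2, sort_keys=True))
    return path


def read_calibration_json(path: str | Path) -> CalibrationFactors:
    return CalibrationFactors.from_dict(json.loads(Path(path).read_text()))


def write_truth_tiff(truth: dict[str, np.ndarray], path: str | Path) -> Path:
    """Ground-truth composition maps as multi-channel float TIFF."""
    path = Path(path)
    names = sorted(truth)
    tifffile.imwrite(
        path, np.stack([truth[n] for n in names]).astype(np.float32),
        photometric="minisblack",
    )
    _write_sidecar(path, {"channels": names, "content": "ground-truth fractions"})
    return path


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_phasor_plot(
    field: PhasorField,
    n: int = 1,
    component_overlay: ComponentSet | None = None,
    bins: int = 256,
    window: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 0.6),
    lifetime_wedge: bool = False,
):
    """Phasor plot: 2-D histogram of (g, s) with the universal semicircle.

    Optionally overlays the component vertices and the connecting
    tetragon, and a fan of constant-phase (iso-lifetime) rays.  Returns a
    matplotlib Figure; deterministic given its inputs.
    """
    from matplotlib.figure import Figure

    gmin, gmax, smin, smax = window
    keep = field.defined
    g = field.g[n][keep]
    s = field.s[n][keep]
    w = np.asarray(field.intensity, dtype=float)[keep]
    fig = Figure(figsize=(5, 3.2), dpi=150)
    ax = fig.add_subplot(111)
    if g.size:
        h, xe, ye = np.histogram2d(
            g, s, bins=bins, range=[[gmin, gmax], [smin, smax]], weights=w
        )
        ax.imshow(
            np.log1p(h.T),
            origin="lower",
            extent=(gmin, gmax, smin, smax),
            aspect="auto",
            cmap="inferno",
        )
    phi = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(phi), 0.5 * np.sin(phi), "w--", lw=0.8)
    if lifetime_wedge:
        acq = field.acquisition
        for tau in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            gs, ss = analytic_phasor(tau, n, acq)
            ax.plot([0, 2 * gs], [0, 2 * ss], color="0.7", lw=0.5)
    if component_overlay is not None:
        pts = [c.phasor(n, field.acquisition) for c in component_overlay]
        ring = pts + pts[:1]
        ax.plot(*zip(*ring), "w:", lw=1.0)
        for c, (gg, ss) in zip(component_overlay, pts):
            ax.plot(gg, ss, "o", ms=5, label=f"{c.name} ({c.tau:g} ns)")
        ax.legend(fontsize=5, loc="upper right")
    ax.set_xlim(gmin, gmax)
    ax.set_ylim(smin, smax)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_title(f"harmonic {n}")
    return fig


def save_figure(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, metadata={"Software": "skinphasor"})
    return path


# ---------------------------------------------------------------------------
# Pipeline configuration and runner
# ---------------------------------------------------------------------------


class AcquisitionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rep_rate_hz: float = 80e6
    n_bins: int = 32
    irf_sigma_ns: float = 0.35
    phase_offset_rad: float = 0.0
    mod_loss: float = 1.0

    def build(self) -> AcquisitionModel:
        return AcquisitionModel(
            rep_rate=self.rep_rate_hz,
            n_bins=self.n_bins,
            irf_sigma=self.irf_sigma_ns,
            phase_offset=self.phase_offset_rad,
            mod_loss=self.mod_loss,
        )


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: str = "depth_series_typeV"
    shape: tuple[int, int] = (128, 128)
    depths: list[float] = Field(default_factory=lambda: [0.0, 15.0, 30.0, 45.0, 60.0])
    mean_photons: float = DEFAULT_MEAN_PHOTONS
    noise: bool = True


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_name: str = "coumarin6"
    reference_tau_ns: float = 2.5
    reference_shape: tuple[int, int] = (64, 64)
    noise: bool = False


class ProcessingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_factor: int = DEFAULT_BIN_FACTOR
    median_kernel: int = 3
    median_passes: int = 1
    min_photons: float = DEFAULT_MIN_PHOTONS


class MaskingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    exclude_large_keratin: bool = False
    f_threshold: float = DEFAULT_KERATIN_THRESHOLD
    min_area: int = DEFAULT_KERATIN_MIN_AREA


class QuantifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    statistics: list[str] = Field(default_factory=lambda: ["p10", "p50", "p90", "mode"])
    trend_statistic: str = "p50"


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    processing: ProcessingConfig = Field(default_factory=ProcessingConfig)
    masking: MaskingConfig = Field(default_factory=MaskingConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    components: list[tuple[str, float]] | Literal["default"] = "default"
    seed: int = 0
    outdir: str = "skinphasor_out"

    @field_validator("components")
    @classmethod
    def _check_components(cls, v):
        if v != "default":
            ComponentSet.from_pairs(v)  # validates count/uniqueness
        return v

    def component_set(self) -> ComponentSet:
        if self.components == "default":
            return ComponentSet.default()
        return ComponentSet.from_pairs(self.components)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix == ".json"
            else yaml.safe_load(text)
        )
        return cls.model_validate(data or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> calibrate -> phasor -> process -> unmix -> quantify.

    Writes every intermediate artifact under ``config.outdir`` and
    returns (and writes) a manifest recording the effective config, the
    seeds, per-stage status/wall time, and a checksum of every numeric
    artifact.  Re-running with the same config reproduces the numeric
    outputs bit-identically.
    """
    import pandas as pd

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "config": config.model_dump(mode="json"),
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }
    artifacts = manifest["artifacts"]

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start (seed=%d)", name, config.seed)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                status = "ok" if exc is None else f"failed: {exc}"
                manifest["stages"].append(
                    {"stage": name, "status": status, "wall_s": round(dt, 4)}
                )
                logger.info("stage %s: %s (%.2fs)", name, status, dt)
                if exc is not None:
                    (out / "manifest.json").write_text(
                        json.dumps(manifest, indent=2, sort_keys=True)
                    )
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    acq = config.acquisition.build()
    components = config.component_set()
    rng_seeds = np.random.SeedSequence(config.seed).spawn(2)
    phantom_seed = int(rng_seeds[0].generate_state(1)[0] % (2**31))
    ref_seed = int(rng_seeds[1].generate_state(1)[0] % (2**31))

    with stage("simulate"):
        spec = PhantomSpec(
            preset=config.simulate.preset,
            shape=tuple(config.simulate.shape),
            depths=config.simulate.depths,
            mean_photons=config.simulate.mean_photons,
            seed=phantom_seed,
        )
        phantom = make_phantom(spec, components, acq, noise=config.simulate.noise)
        for label, stk, truth in zip(phantom.labels, phantom.stacks, phantom.truth):
            write_decay_tiff(
                stk, out / f"stack_{label}.tif", preset=spec.preset, seed=spec.seed
            )
            record(out / f"stack_{label}.tif")
            write_truth_tiff(truth, out / f"truth_{label}.tif")
            record(out / f"truth_{label}.tif")

    with stage("calibrate"):
        ref = make_monoexponential_stack(
            config.calibration.reference_tau_ns,
            tuple(config.calibration.reference_shape),
            config.simulate.mean_photons,
            acq,
            noise=config.calibration.noise,
            seed=ref_seed,
        )
        cal = compute_calibration(
            ref,
            config.calibration.reference_tau_ns,
            reference_name=config.calibration.reference_name,
        )
        write_calibration_json(cal, out / "calibration.json")
        record(out / "calibration.json")

    rows = []
    per_depth: dict[str, list] = {}
    with stage("phasor+process+unmix"):
        for label, stk, truth in zip(phantom.labels, phantom.stacks, phantom.truth):
            field = apply_calibration(phasor_transform(stk), cal)
            field = bin_spatial(field, config.processing.bin_factor)
            field = median_filter_phasor(
                field,
                config.processing.median_kernel,
                config.processing.median_passes,
            )
            write_phasor_tiff(field, out / f"phasor_{label}.tif", cal=cal)
            record(out / f"phasor_{label}.tif")
            keep = threshold_mask(field, config.processing.min_photons)
            fractions = unmix(field, components, mask=keep)
            if config.masking.exclude_large_keratin:
                excl = mask_large_keratin_features(
                    fractions, config.masking.f_threshold, config.masking.min_area
                )
                keep = keep & ~excl
                fractions = unmix(field, components, mask=keep)
            write_fraction_tiff(fractions, out / f"fractions_{label}.tif")
            record(out / f"fractions_{label}.tif")
            write_mask_tiff(keep, out / f"mask_{label}.tif")
            record(out / f"mask_{label}.tif")
            per_depth[label] = [stk.z, fractions, keep]

    with stage("quantify"):
        trend_series: dict[str, list] = {}
        for label, (z, fractions, keep) in per_depth.items():
            dists = {
                name: violin_summary(fractions, name) for name in components.names
            }
            ratio = bound_nadh_ratio(fractions)
            dists["bound_nadh_ratio"] = ratio_summary(ratio, fractions.intensity)
            for name, dist in dists.items():
                summ = dist.summary()
                for statname in config.quantify.statistics:
                    rows.append(
                        {
                            "depth_um": z,
                            "plane": label,
                            "component": name,
                            "statistic": statname,
                            "value": dist.statistic(statname),
                            "n_pixels": summ["n_pixels"],
                            "total_photons": summ["total_photons"],
                        }
                    )
                if z is not None:
                    trend_series.setdefault(name, []).append((z, dist))
        trends = []
        for name, series in trend_series.items():
            if len(series) >= 2:
                tr = depth_trend(series, config.quantify.trend_statistic)
                trends.append(
                    {
                        "component": name,
                        "statistic": tr.statistic_name,
                        "slope_per_um": tr.slope,
                        "intercept": tr.intercept,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
        record(out / "summary.csv")
        (out / "trends.json").write_text(json.dumps(trends, indent=2, sort_keys=True))
        record(out / "trends.json")

    with stage("render"):
        label = phantom.labels[-1]
        field = read_phasor_tiff(out / f"phasor_{label}.tif")
        fig = render_phasor_plot(field, n=1, component_overlay=components)
        save_figure(fig, out / f"phasor_{label}.png")
        fractions = read_fraction_tiff(out / f"fractions_{label}.tif")
        rgb = combined_fraction_map(fractions)
        from matplotlib.figure import Figure

        fig2 = Figure(figsize=(4, 4), dpi=150)
        ax = fig2.add_subplot(111)
        ax.imshow(rgb)
        ax.set_axis_off()
        save_figure(fig2, out / f"fractions_{label}.png")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
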