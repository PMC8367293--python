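"""Histogram CSV input/output, run configuration, and fixture bundles.

Histogram files are plain CSV with `# key=value` header comment lines
(`rep_period_ps`, `bin_width_ps`, `channel`, `integration_time_s`) followed
by `time_ps,counts` rows; time values are 0-based bin centers in ps.
Ground truth for synthetic data travels in JSON sidecars.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .datatypes import (
    AcquisitionSettings,
    AnisotropyParams,
    BindingCondition,
    DecayHistogram,
    EnvironmentModel,
    IRFKernel,
    MultiExpParams,
)
from . import simulate as sim

__all__ = [
    "read_histogram",
    "write_histogram",
    "read_irf",
    "write_irf",
    "RunConfig",
    "load_config",
    "config_hash",
    "make_fixtures",
]

_REQUIRED_KEYS = ("rep_period_ps", "bin_width_ps", "channel", "integration_time_s")


def _parse_header(lines) -> dict:
    meta = {}
    data_start = 0
    for i, line in enumerate(lines):
        line = line.rstrip("\r\n")
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
        elif line:
            data_start = i
            break
    else:
        raise ValueError("no data rows found")
    return meta, data_start


def _read_table(path: Union[str, Path], expected_header: str):
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, data_start = _parse_header(lines)
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise ValueError(f"missing required header key {key!r} in {path.name}")
    header = lines[data_start].strip()
    if header != expected_header:
        raise ValueError(
            f"expected column header {expected_header!r}, found {header!r}"
        )
    times, values = [], []
    for ln in lines[data_start + 1 :]:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise ValueError(f"malformed data row {ln!r}")
        times.append(float(parts[0]))
        values.append(parts[1])
    times = np.asarray(times)
    if times.size < 2:
        raise ValueError("histogram must contain at least two bins")
    diffs = np.diff(times)
    bin_width = float(meta["bin_width_ps"])
    if not np.allclose(diffs, bin_width, rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time grid: bin spacing does not match bin_width_ps")
    settings = AcquisitionSettings(
        n_bins=times.size,
        bin_width=bin_width,
        rep_period=float(meta["rep_period_ps"]),
        photon_budget=0.0,
        integration_time=float(meta["integration_time_s"]),
    )
    return meta, settings, values


def read_histogram(path: Union[str, Path]) -> DecayHistogram:
    """Read a decay histogram CSV; the inverse of :func:`write_histogram`."""
    meta, settings, raw = _read_table(path, "time_ps,counts")
    counts = []
    for v in raw:
        f = float(v)
        if f != int(f):
            raise ValueError(f"non-integer photon count {v!r}")
        counts.append(int(f))
    counts = np.asarray(counts, dtype=float)
    settings = AcquisitionSettings(
        n_bins=settings.n_bins,
        bin_width=settings.bin_width,
        rep_period=settings.rep_period,
        photon_budget=float(counts.sum()),
        integration_time=settings.integration_time,
    )
    return DecayHistogram(counts=counts, settings=settings, channel=meta["channel"])


def write_histogram(
    hist: DecayHistogram, path: Union[str, Path], extra_meta: Optional[dict] = None
) -> None:
    """Write a decay histogram as CSV with metadata header comments."""
    counts = hist.counts
    if np.any(counts != np.round(counts)):
        raise ValueError("histogram counts must be integers; got fractional values")
    s = hist.settings
    lines = [
        f"# rep_period_ps={s.rep_period!r}",
        f"# bin_width_ps={s.bin_width!r}",
        f"# channel={hist.channel}",
        f"# integration_time_s={s.integration_time!r}",
    ]
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k}={v}")
    lines.append("time_ps,counts")
    for t, c in zip(s.time_axis, counts):
        lines.append(f"{t:.6f},{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_irf(path: Union[str, Path]) -> IRFKernel:
    """Read an IRF kernel CSV written by :func:`write_irf`."""
    meta, settings, raw = _read_table(path, "time_ps,weight")
    values = np.asarray([float(v) for v in raw])
    return IRFKernel(
        center=float(meta.get("center_ps", settings.time_axis[np.argmax(values)])),
        fwhm=float(meta.get("fwhm_ps", 0.0) or np.nan),
        values=values / values.sum(),
    )


def write_irf(
    irf: IRFKernel, settings: AcquisitionSettings, path: Union[str, Path]
) -> None:
    """Write an IRF kernel as CSV (float weights, channel=irf)."""
    lines = [
        f"# rep_period_ps={settings.rep_period!r}",
        f"# bin_width_ps={settings.bin_width!r}",
        "# channel=irf",
        f"# integration_time_s={settings.integration_time!r}",
        f"# center_ps={irf.center!r}",
        f"# fwhm_ps={irf.fwhm!r}",
        "time_ps,weight",
    ]
    for t, v in zip(settings.time_axis, irf.values):
        lines.append(f"{t:.6f},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run configuration


class SettingsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_bins: int = 4096
    bin_width_ps: float = 6.1035
    rep_period_ps: float = 25_000.0
    photon_budget: float = 1e6
    integration_time_s: float = 2.0

    def build(self) -> AcquisitionSettings:
        return AcquisitionSettings(
            n_bins=self.n_bins,
            bin_width=self.bin_width_ps,
            rep_period=self.rep_period_ps,
            photon_budget=self.photon_budget,
            integration_time=self.integration_time_s,
        )


class IRFConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    center_ps: float = 1000.0
    fwhm_ps: float = 200.0

    def build(self, settings: AcquisitionSettings) -> IRFKernel:
        return sim.gaussian_irf(settings, center=self.center_ps, fwhm=self.fwhm_ps)


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lifetimes_ps: list
    fractions: list
    background: float = 0.0

    def build(self) -> MultiExpParams:
        return MultiExpParams(
            lifetimes=tuple(self.lifetimes_ps),
            fractions=tuple(self.fractions),
            background=self.background,
        )


class AnisotropyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r0: float = 0.35
    theta_ps: float = 15_900.0
    g_factor: float = 1.0

    def build(self) -> AnisotropyParams:
        return AnisotropyParams(r0=self.r0, theta=self.theta_ps, g_factor=self.g_factor)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    settings: SettingsConfig = Field(default_factory=SettingsConfig)
    irf: IRFConfig = Field(default_factory=IRFConfig)
    model: Optional[ModelConfig] = None
    anisotropy: Optional[AnisotropyConfig] = None
    seed: int = 0
    outdir: Optional[str] = None


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration for output provenance headers."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Canonical fixture bundle


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def make_fixtures(outdir: Union[str, Path], master_seed: int = 0) -> dict:
    """Write the canonical synthetic dataset bundle with ground-truth sidecars.

    Deterministic for a given master seed (byte-identical across runs).
    The bundle covers the canonical conditions: free NADH at 25 and 37 degC,
    fully LDH-bound NADH, a polarized channel triplet, a 25-45 degC
    temperature series, and an LDH titration over [LDH]:[NADH] ratios
    0 to 4. Returns a manifest dict (also written as manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = AcquisitionSettings()
    irf200 = sim.gaussian_irf(settings, center=1000.0, fwhm=200.0)
    irf35 = sim.gaussian_irf(settings, center=1000.0, fwhm=35.0)
    files = []

    def note(p: Path):
        files.append(str(p.relative_to(outdir)))

    for name, irf in (("irf_200ps", irf200), ("irf_35ps", irf35)):
        p = outdir / f"{name}.csv"
        write_irf(irf, settings, p)
        note(p)

    simple = [
        ("free_nadh_25C", sim.FREE_NADH_25C, irf200, master_seed + 11),
        ("free_nadh_37C", sim.FREE_NADH_37C, irf200, master_seed + 12),
        ("bound_nadh", sim.BOUND_NADH, irf35, master_seed + 13),
    ]
    for name, params, irf, seed in simple:
        hist = sim.simulate_decay(params, settings, irf, seed)
        p = outdir / f"{name}_magic.csv"
        write_histogram(hist, p, extra_meta={"seed": seed, "master_seed": master_seed})
        note(p)
        truth = {
            "lifetimes_ps": list(params.lifetimes),
            "fractions": list(params.fractions),
            "photon_budget": settings.photon_budget,
            "irf_fwhm_ps": irf.fwhm,
            "irf_center_ps": irf.center,
            "seed": seed,
        }
        jp = outdir / f"{name}.json"
        _dump_json(truth, jp)
        note(jp)

    # polarized triplet of fully bound NADH (per-channel budget ~1e6)
    pol_dir = outdir / "polarized"
    pol_dir.mkdir(exist_ok=True)
    pol_seed = master_seed + 21
    triplet = sim.simulate_polarized(
        sim.BOUND_NADH,
        sim.BOUND_ANISOTROPY,
        settings,
        irf35,
        pol_seed,
        photon_budget=3.0 * settings.photon_budget,
    )
    for hist in triplet:
        p = pol_dir / f"bound_{hist.channel}.csv"
        write_histogram(hist, p, extra_meta={"seed": pol_seed, "master_seed": master_seed})
        note(p)
    jp = pol_dir / "bound_polarized.json"
    _dump_json(
        {
            "lifetimes_ps": list(sim.BOUND_NADH.lifetimes),
            "fractions": list(sim.BOUND_NADH.fractions),
            "r0": sim.BOUND_ANISOTROPY.r0,
            "theta_ps": sim.BOUND_ANISOTROPY.theta,
            "g_factor": sim.BOUND_ANISOTROPY.g_factor,
            "photon_budget_total": 3.0 * settings.photon_budget,
            "irf_fwhm_ps": irf35.fwhm,
            "seed": pol_seed,
        },
        jp,
    )
    note(jp)

    # temperature series, 25-45 degC
    temp_dir = outdir / "temperature"
    temp_dir.mkdir(exist_ok=True)
    env = EnvironmentModel(reference_params=sim.FREE_NADH_25C)
    temps = [25.0, 29.0, 33.0, 37.0, 41.0, 45.0]
    records = sim.simulate_condition_series(env, temps, settings, irf200, master_seed + 31)
    truth_rows = []
    for rec in records:
        p = temp_dir / f"T{rec.condition:.1f}_magic.csv"
        write_histogram(rec.histograms["magic"], p, extra_meta={"master_seed": master_seed})
        note(p)
        truth_rows.append(rec.truth)
    jp = temp_dir / "temperature.json"
    _dump_json({"series": truth_rows, "slopes": {
        "taum_ps_per_degC": env.taum_slope,
        "intensity_per_degC": env.intensity_slope,
    }}, jp)
    note(jp)

    # LDH titration, ratios 0-4 (Kd is a simulation input, not a literature value)
    tit_dir = outdir / "titration"
    tit_dir.mkdir(exist_ok=True)
    nadh = 12.5  # uM
    kd = 1.5  # uM, synthetic choice
    ratios = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
    conds = [
        BindingCondition(nadh_total=nadh, ldh_total=r * nadh, kd=kd, sites_per_protein=1)
        for r in ratios
    ]
    model = sim.TitrationModel(free_shape=sim.FREE_NADH_37C, bound_shape=sim.BOUND_NADH)
    records = sim.simulate_condition_series(model, conds, settings, irf35, master_seed + 41)
    truth_rows = []
    for rec, ratio in zip(records, ratios):
        p = tit_dir / f"ratio_{ratio:.2f}_magic.csv"
        write_histogram(rec.histograms["magic"], p, extra_meta={"master_seed": master_seed})
        note(p)
        truth_rows.append(rec.truth)
    jp = tit_dir / "titration.json"
    _dump_json(
        {
            "series": truth_rows,
            "kd_uM": kd,
            "nadh_uM": nadh,
            "free_shape": {
                "lifetimes_ps": list(sim.FREE_NADH_37C.lifetimes),
                "fractions": list(sim.FREE_NADH_37C.fractions),
            },
            "bound_shape": {
                "lifetimes_ps": list(sim.BOUND_NADH.lifetimes),
                "fractions": list(sim.BOUND_NADH.fractions),
            },
        },
        jp,
    )
    note(jp)

    manifest = {"master_seed": master_seed, "files": sorted(files)}
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
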