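"""Config-driven workflow: model build -> segmentation -> absorption /
emission / couplings -> rate -> thermal correction -> kinetics.

Each stage reads its inputs from the output directory (or from paths in the
config), writes its artifacts there, and can be re-run independently — e.g.
after replacing the intersegment couplings only the rate stage needs to be
repeated.  All randomness derives from one master seed.  Warnings raised by
any stage are echoed to the log and collected in ``warnings.json``.
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .errors import ConfigError
from .kinetics import (
    build_rate_matrix,
    eigen_analysis,
    incoherence_check,
    propagate_populations,
)
from .models import (
    DisorderModel,
    build_parallel_chains,
    build_ring,
    build_trajectory,
    point_dipole_couplings,
)
from .rates import (
    SamplingSpec,
    ThermalSpec,
    absorption_matrix,
    decoherence_rate,
    emission_matrix,
    integrate_rate,
    rate_response,
)
from .segmentation import adm_matrix, cluster_segments
from .thermal import SegmentEnergies, delta_e_adjustment, segment_energy, thermal_correction

log = logging.getLogger("mcfret")

STAGES = ("generate", "segment", "absorption", "emission", "rate", "correct", "kinetics")

_DEFAULTS = {
    "system": "chains",
    "n_per_chain": 2,
    "spacing": 0.95,
    "separation": 1.5,
    "slip": 0.0,
    "dipole": 11.4,
    "n_sites": 18,
    "radius": 3.0,
    "ring_distance": 7.5,
    "mean_energy": 0.0,
    "screening": 1.0,
    "sigma_dyn": 1500.0,
    "tau_dyn": 6.0,
    "sigma_static": 0.0,
    "tau_static": 10000.0,
    "static_mode": "ou",  # "ou" | "frozen"
    "n_frames": 5000,
    "dt": 3.0,
    "seed": 1,
    "t_c": 72.0,
    "temperature": 300.0,
    "ht": False,
    "n_samples": 100,
    "interval": 20,
    "epsilon_p": 0.4,
    "adm_stride": 10,
    "equilibrium": "instantaneous",
    "thermal_correction": True,
    "delta_e": False,
    "energy_stride": 50,
    "simpson_threshold": 0.03,
    "threads": 1,
    "imag_tolerance": 1e-8,
    "outdir": "mcfret_out",
    "trajectory": "",
    "couplings": "",
    "geometry": "",
    "segmentation": "",
}

_BOOL_KEYS = {"ht", "thermal_correction", "delta_e"}
_INT_KEYS = {
    "n_per_chain", "n_sites", "n_frames", "seed", "n_samples", "interval",
    "adm_stride", "energy_stride", "threads",
}
_STR_KEYS = {
    "system", "static_mode", "equilibrium", "outdir", "trajectory", "couplings",
    "geometry", "segmentation",
}


@dataclass
class RunConfig:
    """Validated flat configuration; see ``_DEFAULTS`` for keys and defaults."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        problems = []
        cfg = dict(_DEFAULTS)
        for key, raw in self.values.items():
            if key not in _DEFAULTS:
                problems.append(f"unknown config key {key!r}")
                continue
            try:
                cfg[key] = _coerce(key, raw)
            except (TypeError, ValueError) as exc:
                problems.append(f"bad value for {key!r}: {exc}")
        if not problems:
            if cfg["dt"] <= 0:
                problems.append("dt must be > 0")
            n_steps = cfg["t_c"] / cfg["dt"]
            if abs(round(n_steps) - n_steps) > 1e-9:
                problems.append("t_c must be a multiple of dt")
            if not cfg["ht"] and cfg["temperature"] <= 0:
                problems.append("temperature must be > 0 (or set ht)")
            for key in ("trajectory", "couplings", "geometry", "segmentation"):
                if cfg[key] and not Path(cfg[key]).exists():
                    problems.append(f"{key} file not found: {cfg[key]}")
        if problems:
            raise ConfigError("; ".join(problems))
        self.values = cfg

    def __getitem__(self, key):
        return self.values[key]

    @property
    def outdir(self) -> Path:
        return Path(self.values["outdir"])

    @property
    def thermal(self) -> ThermalSpec:
        if self["ht"]:
            return ThermalSpec(mode="ht")
        return ThermalSpec(temperature=self["temperature"])

    @property
    def sampling(self) -> SamplingSpec:
        return SamplingSpec(n_samples=self["n_samples"], interval=self["interval"])

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(values=parse_config_file(path))


def _coerce(key, raw):
    if isinstance(raw, str):
        raw = raw.strip()
    if key in _STR_KEYS:
        return str(raw)
    if key in _BOOL_KEYS:
        if isinstance(raw, bool):
            return raw
        if str(raw).lower() in ("1", "true", "yes", "on"):
            return True
        if str(raw).lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    if key in _INT_KEYS:
        return int(raw)
    return float(raw)


def parse_config_file(path) -> dict:
    """Read a flat ``key = value`` (or ``key value``) text config."""
    values = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        else:
            key, _, val = line.partition(" ")
        key, val = key.strip(), val.strip()
        if not key or not val:
            raise ConfigError(f"{path}:{lineno}: cannot parse line {line!r}")
        values[key] = val
    return values


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _load_trajectory(config: RunConfig):
    out = config.outdir
    cpath = config["couplings"] or out / "couplings.txt"
    tpath = config["trajectory"] or out / "energies.traj"
    for p, stage in ((cpath, "generate (couplings)"), (tpath, "generate (trajectory)")):
        if not Path(p).exists():
            raise ConfigError(f"missing input artifact {p}; run stage '{stage}' first")
    return mio.read_trajectory(tpath, mio.read_couplings(cpath))


def _load_segments(config: RunConfig):
    path = config["segmentation"] or config.outdir / "segmentation.txt"
    if not Path(path).exists():
        raise ConfigError(f"missing segmentation {path}; run stage 'segment' first")
    return mio.segments_from_assignment(mio.read_segmentation(path))


def stage_generate(config: RunConfig) -> None:
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    if config["geometry"]:
        system = mio.read_geometry(config["geometry"])
    elif config["system"] == "chains":
        system = build_parallel_chains(
            config["n_per_chain"], config["spacing"], config["separation"],
            config["slip"], config["dipole"], config["mean_energy"],
            config["screening"],
        )
    elif config["system"] == "ring_pair":
        r1 = build_ring(
            config["n_sites"], config["radius"], config["dipole"],
            mean_energy=config["mean_energy"], screening=config["screening"],
        )
        r2 = build_ring(
            config["n_sites"], config["radius"], config["dipole"],
            center=(config["ring_distance"], 0.0, 0.0),
            mean_energy=config["mean_energy"], screening=config["screening"],
        )
        system = r1.concatenate([r1, r2])
    else:
        raise ConfigError(f"unknown system {config['system']!r}")
    components = [(config["sigma_dyn"], config["tau_dyn"])]
    if config["sigma_static"] > 0 and config["static_mode"] == "ou":
        components.append((config["sigma_static"], config["tau_static"]))
    traj = build_trajectory(
        system, DisorderModel(components), config["n_frames"], config["dt"],
        seed=config["seed"],
    )
    if config["sigma_static"] > 0 and config["static_mode"] == "frozen":
        # one frozen offset per site for the explicit static-disorder batch mode
        rng = np.random.default_rng(np.random.SeedSequence([config["seed"], 2**20]))
        traj.energies += config["sigma_static"] * rng.standard_normal(system.n_sites)
    mio.write_geometry(out / "geometry.txt", system)
    mio.write_couplings(out / "couplings.txt", traj.couplings)
    mio.write_trajectory(out / "energies.traj", traj)
    log.info("generate: %d sites, %d frames", system.n_sites, traj.n_frames)


def stage_segment(config: RunConfig) -> None:
    traj = _load_trajectory(config)
    adm = adm_matrix(traj, stride=config["adm_stride"])
    seg = cluster_segments(adm, config["epsilon_p"])
    out = config.outdir
    np.savetxt(out / "adm.csv", adm.values, delimiter=",", fmt="%.8g")
    if seg.linkage is not None:
        np.savetxt(out / "linkage.csv", seg.linkage, delimiter=",", fmt="%.8g")
    mio.write_segmentation(out / "segmentation.txt", seg.assignment)
    log.info("segment: %d segments at eps_p=%g", seg.n_segments, config["epsilon_p"])


def stage_absorption(config: RunConfig) -> None:
    traj = _load_trajectory(config)
    segments = _load_segments(config)
    series = {
        f"segment_{i + 1}": absorption_matrix(
            traj, seg, config["t_c"], config.sampling
        ).values
        for i, seg in enumerate(segments)
    }
    np.savez(config.outdir / "absorption.npz", dt=traj.dt, **series)
    log.info("absorption: %d segments", len(segments))


def stage_emission(config: RunConfig) -> None:
    traj = _load_trajectory(config)
    segments = _load_segments(config)
    series = {
        f"segment_{i + 1}": emission_matrix(
            traj, seg, config["t_c"], config.thermal, config.sampling,
            config["equilibrium"],
        ).values
        for i, seg in enumerate(segments)
    }
    np.savez(config.outdir / "emission.npz", dt=traj.dt, **series)
    log.info("emission: %d segments", len(segments))


def stage_rate(config: RunConfig) -> None:
    from .rates import MatrixSeries

    out = config.outdir
    for name in ("absorption.npz", "emission.npz"):
        if not (out / name).exists():
            raise ConfigError(f"missing input artifact {out / name}; run stage "
                              f"'{name.split('.')[0]}' first")
    traj = _load_trajectory(config)
    segments = _load_segments(config)
    absd = np.load(out / "absorption.npz")
    emsd = np.load(out / "emission.npz")
    dt = float(absd["dt"])
    J = traj.static_couplings()
    n_seg = len(segments)
    K = np.zeros((n_seg, n_seg))
    G = np.zeros((n_seg, n_seg))
    warn_flag = False
    for d in range(n_seg):
        for a in range(n_seg):
            if d == a:
                continue
            I = MatrixSeries("absorption", absd[f"segment_{a + 1}"], dt, config["n_samples"])
            E = MatrixSeries("emission", emsd[f"segment_{d + 1}"], dt, config["n_samples"])
            block = J[np.ix_(segments[a], segments[d])]
            R = rate_response(I, E, block, donor=d, acceptor=a)
            res = integrate_rate(R, config["simpson_threshold"])
            warn_flag = warn_flag or res.quadrature_warning
            K[a, d] = res.rate
            G[a, d] = decoherence_rate(R)
            np.savetxt(
                out / f"response_{d + 1}_to_{a + 1}.csv",
                np.column_stack([R.times, R.values.real, R.values.imag]),
                delimiter=",", header="t_fs,re,im", comments="",
            )
    np.savetxt(out / "rate_matrix.txt", K, fmt="%.6f",
               header="raw rates ps^-1, rows=to, cols=from", comments="# ")
    np.savetxt(out / "gamma_matrix.txt", G, fmt="%.6f",
               header="decoherence rates ps^-1, rows=to, cols=from", comments="# ")
    with open(out / "rate_report.json", "w") as fh:
        json.dump({"rate_matrix_ps_inv": K.tolist(), "gamma_ps_inv": G.tolist(),
                   "quadrature_warning": warn_flag}, fh, indent=1)
    log.info("rate: %d segment pairs", n_seg * (n_seg - 1))


def stage_correct(config: RunConfig) -> None:
    out = config.outdir
    kpath = out / "rate_matrix.txt"
    if not kpath.exists():
        raise ConfigError(f"missing input artifact {kpath}; run stage 'rate' first")
    K_off = np.atleast_2d(np.loadtxt(kpath))
    K = build_rate_matrix(K_off).K
    if not config["thermal_correction"]:
        np.savetxt(out / "corrected_rate_matrix.txt", K, fmt="%.6f",
                   header="uncorrected rates ps^-1, rows=to, cols=from", comments="# ")
        return
    traj = _load_trajectory(config)
    segments = _load_segments(config)
    thermal = config.thermal
    energies = np.array([
        segment_energy(traj, seg, thermal, stride=config["energy_stride"])
        for seg in segments
    ])
    D = np.array([len(s) for s in segments])
    delta = None
    if config["delta_e"]:
        P_raw = eigen_analysis(build_rate_matrix(K_off), config["imag_tolerance"]).equilibrium
        delta = delta_e_adjustment(P_raw, D, thermal)
    seg_e = SegmentEnergies(energies=energies, site_counts=D, delta_e=delta)
    Kc = thermal_correction(K, seg_e, thermal)
    np.savetxt(out / "segment_energies.txt",
               np.column_stack([seg_e.effective(), D]), fmt="%.6f",
               header="effective segment energy cm^-1, site count", comments="# ")
    np.savetxt(out / "corrected_rate_matrix.txt", Kc, fmt="%.6f",
               header="thermally corrected rates ps^-1, rows=to, cols=from", comments="# ")
    log.info("correct: segment energies %s cm^-1", np.round(seg_e.effective(), 1))


def stage_kinetics(config: RunConfig) -> None:
    out = config.outdir
    kpath = out / "corrected_rate_matrix.txt"
    if not kpath.exists():
        kpath = out / "rate_matrix.txt"
    if not kpath.exists():
        raise ConfigError(f"missing input artifact {kpath}; run stage 'rate' first")
    K = build_rate_matrix(np.atleast_2d(np.loadtxt(kpath)))
    report = eigen_analysis(K, config["imag_tolerance"])
    gpath = out / "gamma_matrix.txt"
    coherence = []
    if gpath.exists():
        G = np.atleast_2d(np.loadtxt(gpath))
        coherence = [
            {"from": c.donor + 1, "to": c.acceptor + 1, "rate": c.rate,
             "gamma": c.gamma, "label": c.label}
            for c in incoherence_check(K, G)
        ]
    n = K.n_segments
    P0 = np.zeros(n)
    P0[-1] = 1.0  # start in the highest-energy segment
    times = np.linspace(0.0, 20_000.0, 201)  # fs
    P = propagate_populations(K, P0, times)
    np.savetxt(out / "populations.csv", np.column_stack([times, P]), delimiter=",",
               header="t_fs," + ",".join(f"P{i + 1}" for i in range(n)), comments="")
    with open(out / "kinetics_report.json", "w") as fh:
        json.dump({
            "eigenvalues_ps_inv": [complex(v).real for v in report.eigenvalues],
            "relaxation_rates_ps_inv": list(report.relaxation_rates),
            "equilibrium": list(report.equilibrium),
            "complex_eigenvalue_flag": report.complex_flag,
            "coherence": coherence,
        }, fh, indent=1)
    log.info("kinetics: relaxation rates %s ps^-1",
             np.round(report.relaxation_rates, 3))


_STAGE_FUNCS = {
    "generate": stage_generate,
    "segment": stage_segment,
    "absorption": stage_absorption,
    "emission": stage_emission,
    "rate": stage_rate,
    "correct": stage_correct,
    "kinetics": stage_kinetics,
}


def run_workflow(config: RunConfig, stages: tuple[str, ...] = STAGES) -> list[dict]:
    """Run the requested stages in workflow order; returns collected warnings.

    Warnings from every stage go to the log and to ``warnings.json`` in the
    output directory.
    """
    bad = [s for s in stages if s not in _STAGE_FUNCS]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    ordered = [s for s in STAGES if s in stages]
    config.outdir.mkdir(parents=True, exist_ok=True)
    collected: list[dict] = []
    for stage in ordered:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            _STAGE_FUNCS[stage](config)
        for w in caught:
            log.warning("[%s] %s: %s", stage, w.category.__name__, w.message)
            collected.append({
                "stage": stage, "category": w.category.__name__,
                "message": str(w.message),
            })
    wpath = config.outdir / "warnings.json"
    existing = []
    if wpath.exists():
        existing = json.loads(wpath.read_text())
    with open(wpath, "w") as fh:
        json.dump(existing + collected, fh, indent=1)
    return collected


def batch_rates(configs: list[RunConfig], stages: tuple[str, ...] = STAGES) -> dict:
    """Run several configs differing only in the disorder realization and
    summarize the resulting rate distribution (explicit static disorder
    workflow: one rate per trajectory, then the spread is analyzed).
    """
    if len(configs) < 2:
        raise ConfigError("batch mode needs at least 2 configurations")
    segs = {c["segmentation"] for c in configs}
    if len(segs) > 1:
        raise ConfigError(
            "heterogeneous segmentations across batch configs; supply one shared "
            "segmentation file (or run per-config segmentation explicitly)"
        )
    rates = []
    for config in configs:
        run_workflow(config, stages)
        report = json.loads((config.outdir / "rate_report.json").read_text())
        K = np.array(report["rate_matrix_ps_inv"])
        rates.append(K[np.triu_indices_from(K, k=1)].sum() + K[np.tril_indices_from(K, k=-1)].sum())
    rates = np.asarray(rates)
    return {
        "n": len(rates),
        "rates_ps_inv": rates.tolist(),
        "mean": float(rates.mean()),
        "std": float(rates.std(ddof=1)),
        "quantiles": {q: float(np.quantile(rates, float(q))) for q in ("0.1", "0.5", "0.9")},
    }
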