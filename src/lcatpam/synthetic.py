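"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here so the full
stack is testable without MD trajectories or plate-reader exports:

* :func:`gen_trajectory` — replicate pseudo-trajectories whose CYS50–ASN65
  distance follows a stationary Ornstein–Uhlenbeck (OU) process, the minimal
  model of a fluctuating inter-residue distance with tunable mean, variance
  and correlation time;
* :func:`gen_mm_assay` — triplicate Michaelis–Menten fluorescence plates
  with background wells and a noiseless standard-curve block;
* :func:`gen_dose_response` — triplicate 4PL dose–response plates;
* :func:`gen_compound_library` — screening libraries with known
  charge/mass/score composition and exact expected triage counts.

All randomness flows from one integer seed through ``numpy.random``
SeedSequence spawning, so generators are deterministic and independently
re-seedable.  The OU update is exact (not an Euler step):

    d(t+dt) = mu + (d(t) - mu) * exp(-dt/tau) + sd * sqrt(1 - exp(-2 dt/tau)) * z.

Distances are embedded on the x-axis as two pseudo-residues (CYS 50 at the
origin, ASN 65 at (d, 0, 0)), so rigid-body invariance tests can rotate the
frames independently of the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinetics import PlateData
from .screen import CompoundRecord
from .trajectory_io import AtomKey, TrajectoryFrames

__all__ = [
    "TrajectorySpec",
    "AssaySpec",
    "gen_trajectory",
    "gen_ou_series",
    "gen_mm_assay",
    "gen_dose_response",
    "gen_compound_library",
    "gen_activity_study",
]

_NM = 10.0  # Å per nm

#: DHE concentrations (µM) of the acyltransferase plate layout
DHE_CONCS = (0.0, 6.4, 9.6, 14.4, 21.6, 32.5, 50.6)
#: PAM concentrations (µM) of the EC50 titration layout
PAM_CONCS = (0.001, 0.01, 0.1, 1.0, 10.0)


@dataclass
class TrajectorySpec:
    """Ground truth for OU pseudo-trajectories.

    Defaults emulate the replicate-simulation protocol: five 200 ns
    replicates sampled every 0.1 ns, fluctuating around a 2 nm residue-pair
    distance with 0.1 nm stationary SD and a 5 ns correlation time.
    """

    mean_distance: float = 2.0  # nm
    stationary_sd: float = 0.1  # nm
    correlation_time: float = 5.0  # ns
    n_frames: int = 2000
    dt: float = 0.1  # ns
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mean_distance, self.correlation_time, self.dt) <= 0:
            raise ValueError("mean_distance, correlation_time and dt must be > 0")
        if self.stationary_sd < 0:
            raise ValueError("stationary_sd must be >= 0")
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class AssaySpec:
    """Ground truth for Michaelis–Menten plates.

    Defaults generate plates matching the acyltransferase layout: the DHE
    well concentrations, 1 h reaction, triplicates, a 40 AU/µM standard
    curve, 50 AU background, and 2% (of Vmax) Gaussian signal noise around
    Michaelis–Menten truth Vmax = 8.66 µM h⁻¹, Km = 11.59 µM.
    """

    vmax: float = 8.66  # µM/h
    km: float = 11.59  # µM
    substrate_concs: tuple = DHE_CONCS
    noise_sd_fraction: float = 0.02
    n_replicates: int = 3
    time: float = 1.0  # h
    standard_curve_slope: float = 40.0  # AU/µM
    background_mean: float = 50.0  # AU
    condition_label: str = "LCAT"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.vmax, self.km, self.standard_curve_slope, self.time) <= 0:
            raise ValueError("vmax, km, slope and time must be > 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")


def gen_ou_series(
    mean: float, sd: float, tau: float, n: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact stationary OU sample path of length n."""
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    z = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + (x[i - 1] - mean) * a + b * z[i - 1]
    return x


def gen_trajectory(spec: TrajectorySpec) -> list[TrajectoryFrames]:
    """Replicate pseudo-trajectories realizing OU distance paths.

    Each replicate holds two CA atoms — CYS 50 at the origin and ASN 65 at
    (d(t), 0, 0) — so the α-carbon distance pipeline recovers the OU path
    exactly.  Distances are truncated at a small positive floor (1e-6 nm) so
    pathological negative OU excursions never produce an invalid geometry.
    """
    roster = [
        AtomKey(chain_id="A", residue_number=50, atom_name="CA", residue_name="CYS"),
        AtomKey(chain_id="A", residue_number=65, atom_name="CA", residue_name="ASN"),
    ]
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    times = np.arange(spec.n_frames) * spec.dt
    out = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        d_nm = gen_ou_series(
            spec.mean_distance,
            spec.stationary_sd,
            spec.correlation_time,
            spec.n_frames,
            spec.dt,
            rng,
        )
        d_nm = np.maximum(d_nm, 1e-6)
        coords = np.zeros((spec.n_frames, 2, 3))
        coords[:, 1, 0] = d_nm * _NM  # Å
        out.append(
            TrajectoryFrames(
                roster=roster,
                coords=coords,
                times=times.copy(),
                source_label=f"rep{r + 1}",
            )
        )
    return out


def gen_mm_assay(spec: AssaySpec) -> tuple[PlateData, dict]:
    """Michaelis–Menten plate with background and standard-curve blocks.

    Well signal = background + slope·v(S)·time + N(0, noise_sd_fraction ·
    vmax · slope · time); S = 0 wells carry pure background (no enzyme
    product).  The standard-curve block is noiseless.  Returns the plate and
    a ground-truth dict.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []
    noise_sd = spec.noise_sd_fraction * spec.vmax * spec.standard_curve_slope * spec.time
    for rep in range(1, spec.n_replicates + 1):
        for S in spec.substrate_concs:
            v = spec.vmax * S / (spec.km + S) if S > 0 else 0.0
            signal = spec.background_mean + spec.standard_curve_slope * v * spec.time
            if S > 0 and noise_sd > 0:
                signal += noise_sd * rng.standard_normal()
            rows.append(
                {
                    "condition_label": spec.condition_label,
                    "replicate_id": f"rep{rep}",
                    "substrate_conc": S,
                    "signal": signal,
                    "background_signal": spec.background_mean,
                    "time_h": spec.time,
                }
            )
    standards_conc = np.linspace(0, max(spec.substrate_concs), 6)
    standards = pd.DataFrame(
        {
            "conc": standards_conc,
            "signal": spec.standard_curve_slope * standards_conc,
        }
    )
    truth = {
        "vmax": spec.vmax,
        "km": spec.km,
        "standard_curve_slope": spec.standard_curve_slope,
        "background_mean": spec.background_mean,
        "noise_sd_fraction": spec.noise_sd_fraction,
        "condition_label": spec.condition_label,
        "seed": spec.seed,
    }
    return PlateData(wells=pd.DataFrame(rows), standard_curve=standards), truth


def gen_dose_response(
    ec50: float = 0.1,
    top: float = 250.0,
    bottom: float = 100.0,
    hill: float = 1.0,
    concs: tuple = PAM_CONCS,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    condition_label: str = "",
) -> tuple[pd.DataFrame, dict]:
    """4PL responses (percent of control) at the titration concentrations."""
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concs must be positive (zero-dose handled by bottom)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for rep in range(1, n_replicates + 1):
        resp = bottom + (top - bottom) / (
            1.0 + 10.0 ** ((np.log10(ec50) - np.log10(concs)) * hill)
        )
        if noise_sd > 0:
            resp = resp + noise_sd * rng.standard_normal(len(concs))
        for c, r_ in zip(concs, resp):
            rows.append(
                {
                    "condition_label": condition_label,
                    "replicate_id": f"rep{rep}",
                    "conc": c,
                    "response_pct": r_,
                }
            )
    truth = {
        "ec50": ec50,
        "top": top,
        "bottom": bottom,
        "hill": hill,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


def gen_compound_library(
    n: int,
    frac_charged: float = 0.3,
    mass_range: tuple[float, float] = (50.0, 700.0),
    score_mean: float = -6.0,
    score_sd: float = 1.5,
    frac_scored: float = 1.0,
    seed: int = 0,
    mass_min: float = 100.0,
    mass_max: float = 600.0,
    score_cutoff: float = -7.0,
) -> tuple[list[CompoundRecord], dict]:
    """Random screening library plus exact expected triage counts.

    Masses are uniform over ``mass_range`` (wider than the 100–600 g/mol
    window so both tails are exercised), charges Bernoulli(frac_charged),
    SP/XP scores Gaussian.  Expected stage counts under the default triage
    thresholds are recomputed here by direct enumeration over the sampled
    records, independently of the filter implementation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for i in range(n):
        charged = bool(rng.random() < frac_charged)
        mass = float(rng.uniform(*mass_range))
        has_score = bool(rng.random() < frac_scored)
        sp = float(rng.normal(score_mean, score_sd)) if has_score else None
        xp = float(sp + rng.normal(0, 0.3)) if sp is not None else None
        records.append(
            CompoundRecord(
                compound_id=f"cmpd{i:05d}",
                name=f"synthetic compound {i}",
                mass=mass,
                has_charged_group=charged,
                docking_score_sp=sp,
                docking_score_xp=xp,
                diversity_key=f"scaffold{i % max(1, n // 4)}",
            )
        )

    counts = {
        "input": n,
        "after_charge": 0,
        "after_mass": 0,
        "after_score": 0,
        "xp_docked": 0,
        "md_candidates": 0,
    }
    for rec in records:
        if rec.has_charged_group:
            continue
        counts["after_charge"] += 1
        if rec.mass < mass_min or rec.mass > mass_max:
            continue
        counts["after_mass"] += 1
        if rec.docking_score_sp is None or rec.docking_score_sp > score_cutoff:
            continue
        counts["after_score"] += 1
        counts["md_candidates"] += 1
        if rec.docking_score_xp is not None:
            counts["xp_docked"] += 1
    return records, counts


def gen_activity_study(
    n_compounds: int = 5,
    slope: float = 200.0,  # % per nm
    intercept: float = -250.0,  # %
    distance_low: float = 1.8,  # nm
    distance_high: float = 2.4,  # nm
    stationary_sd: float = 0.0,
    activity_noise_sd: float = 0.0,
    n_frames: int = 200,
    dt: float = 1.0,
    n_replicates: int = 5,
    seed: int = 0,
) -> dict:
    """A complete synthetic calibration study with known ground truth.

    ``n_compounds`` pseudo-compounds are assigned evenly spaced true mean
    distances on [distance_low, distance_high] nm; each gets OU replicate
    trajectories around its true distance and a true activity on the line
    activity = slope·distance + intercept (plus optional Gaussian noise).
    With the defaults the activities span 110–230% of control, the range
    reference activators cover.

    Returns a dict with ``compounds`` (id → {true_distance, activity_pct,
    trajectories}) and the generating ``truth`` parameters.  At zero noise
    the distance → calibrate → predict pipeline must recover the activity
    ranking exactly.
    """
    if n_compounds < 3:
        raise ValueError("need >= 3 compounds for a calibration study")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    true_d = np.linspace(distance_low, distance_high, n_compounds)
    compounds = {}
    for i, d in enumerate(true_d):
        cid = f"ref{i + 1}"
        activity = slope * d + intercept
        if activity_noise_sd > 0:
            activity += activity_noise_sd * rng.standard_normal()
        if activity <= 0:
            raise ValueError(
                "generating line yields non-positive activity; adjust parameters"
            )
        spec = TrajectorySpec(
            mean_distance=float(d),
            stationary_sd=stationary_sd,
            correlation_time=5.0,
            n_frames=n_frames,
            dt=dt,
            n_replicates=n_replicates,
            seed=seed * 1000 + i,
        )
        compounds[cid] = {
            "true_distance": float(d),
            "activity_pct": float(activity),
            "trajectories": gen_trajectory(spec),
        }
    return {
        "compounds": compounds,
        "truth": {
            "slope": slope,
            "intercept": intercept,
            "stationary_sd": stationary_sd,
            "activity_noise_sd": activity_noise_sd,
            "seed": seed,
        },
    }
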