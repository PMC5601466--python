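"""Synthetic inputs with the statistical structure the analysis assumes.

The generators stand in for the MD engine so the whole pipeline can be
exercised offline:

* :func:`gen_force_trace` — antisymmetric two-channel pull forces: linear
  loading ramps at an effective stiffness, sawtooth drops at planted
  rupture elongations, iid Gaussian noise per channel, 0.05 ns sampling.
* :func:`gen_bell_ruptures` — rupture forces drawn from the first-passage
  law of a force ramp with Bell-activated rate k(F)=k_off·exp(F·x_b/kT),
  the process whose modal force follows the Bell equation.
* :func:`gen_ca_series` — an equilibrium AR(1) contact-area segment for
  baseline estimation followed by a pulled segment with planted sigmoidal
  losses; noise amplitude scales with the remaining contact.
* :func:`gen_toy_structure` — atom sets with analytically known geometry
  (sphere pairs for SASA oracles, straight Cα rods for contact-area and
  tilt fixtures).
* :func:`gen_order_counts` — binomial first-unfolding counts at a given
  barrier difference through the logistic link.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bayes import OrderCounts, p_from_ddg
from .constants import DEFAULT_TEMPERATURE, kt_pn_nm
from .forces import RuptureRecord
from .geometry import ContactAreaSeries
from .io import ForceTrace, StructureModel

__all__ = [
    "TraceSpec",
    "BellSampleSpec",
    "CaSeriesSpec",
    "SyntheticCaTrajectory",
    "gen_force_trace",
    "gen_bell_ruptures",
    "gen_ca_series",
    "ca_envelope",
    "gen_toy_structure",
    "sphere_pair",
    "helix_pair",
    "helix_pair_frames",
    "tilted_rod",
    "gen_order_counts",
]


@dataclass
class TraceSpec:
    """Recipe for a sawtooth pull-force trace (emulating one FPMD pull)."""

    v_pull: float = 0.1  # nm/ns
    k_eff: float = 50.0  # pN/nm effective loading slope between ruptures
    events: tuple[tuple[float, float], ...] = ()  # (elongation nm, drop fraction)
    noise_sd: float = 0.0  # pN per channel
    duration: float = 250.0  # ns (reaches 25 nm at v=0.1)
    dt: float = 0.05  # ns sampling
    k_spring: float = 830.0  # pN/nm metadata for downstream fits
    label: str = ""

    def __post_init__(self) -> None:
        xs = [x for x, _ in self.events]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("rupture elongations must be increasing")
        if any(not (0 < d <= 1) for _, d in self.events):
            raise ValueError("drop fractions must lie in (0, 1]")


@dataclass
class BellSampleSpec:
    """Recipe for first-passage rupture-force samples on a velocity ladder."""

    x_b: float = 0.3  # nm
    k_off: float = 1e-5  # 1/ns
    k_spring: float = 830.0  # pN/nm
    velocities: tuple[float, ...] = (1.0, 1 / 3, 1 / 10, 1 / 30)  # nm/ns
    replicas: int = 10
    temperature: float = DEFAULT_TEMPERATURE
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.x_b, self.k_off, self.k_spring) <= 0:
            raise ValueError("x_b, k_off, k_spring must be positive")
        if any(v <= 0 for v in self.velocities):
            raise ValueError("velocities must be positive")


@dataclass
class CaSeriesSpec:
    """Recipe for an equilibrium + pulled contact-area trajectory."""

    eq_mean: float = 5.0  # nm²
    ar_coef: float = 0.8  # AR(1) coefficient, in [0, 1)
    innov_sd: float = 0.15  # nm² innovation standard deviation
    events: tuple[tuple[float, float], ...] = ()  # (start elongation nm, width nm)
    n_eq: int = 2000  # equilibrium frames for baseline estimation
    v_pull: float = 1.0  # nm/ns
    dt: float = 0.05  # ns
    duration: float = 60.0  # ns of pulling
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coef < 1:
            raise ValueError("AR coefficient must lie in [0, 1)")
        if any(w <= 0 for _, w in self.events):
            raise ValueError("event widths must be positive")


@dataclass
class SyntheticCaTrajectory:
    """Equilibrium segment plus pulled contact-area series, with planted truth."""

    equilibrium: np.ndarray  # nm², stationary segment
    series: ContactAreaSeries
    spec: CaSeriesSpec


def gen_force_trace(spec: TraceSpec, seed: int) -> ForceTrace:
    """Sawtooth pull-force trace with antisymmetric channels and noise.

    The deterministic force ramps at ``k_eff`` per nm of elongation and drops
    by the planted fraction at each event elongation; channel 1 carries +F,
    channel 2 −F, each plus iid Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration / spec.dt)) + 1
    time = np.arange(n) * spec.dt
    x = spec.v_pull * time
    force = _piecewise_sawtooth(x, spec.k_eff, spec.events)
    eta1 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
    eta2 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
    return ForceTrace(time=time, f1=force + eta1, f2=-force + eta2,
                      v_pull=spec.v_pull, k_spring=spec.k_spring,
                      label=spec.label or f"synthetic-v{spec.v_pull:g}")


def _piecewise_sawtooth(x: np.ndarray, k_eff: float,
                        events: Sequence[tuple[float, float]]) -> np.ndarray:
    force = np.empty_like(x)
    offset = 0.0  # force baseline carried across segments
    prev_x = x[0]
    start = 0
    for x_event, drop in events:
        # a sample at exactly the event elongation still sees the peak force
        seg = slice(start, int(np.searchsorted(x, x_event, side="right")))
        force[seg] = offset + k_eff * (x[seg] - prev_x)
        f_peak = offset + k_eff * (x_event - prev_x)
        offset = f_peak * (1.0 - drop)
        prev_x = x_event
        start = seg.stop
    force[start:] = offset + k_eff * (x[start:] - prev_x)
    return force


def gen_bell_ruptures(spec: BellSampleSpec, seed: int) -> list[RuptureRecord]:
    """Rupture forces sampled from the force-ramp first-passage law.

    For loading rate r = k_spring·v the survival function is
    S(F) = exp[−(k_off·kT)/(r·x_b)·(exp(F·x_b/kT) − 1)]; samples come from
    the exact inverse CDF, one stream for the whole ladder.
    """
    rng = np.random.default_rng(seed)
    kT = kt_pn_nm(spec.temperature)
    records = []
    for v in spec.velocities:
        r = spec.k_spring * v
        scale = r * spec.x_b / (spec.k_off * kT)
        u = rng.uniform(size=spec.replicas)
        f = (kT / spec.x_b) * np.log1p(-scale * np.log(u))
        for i, f_r in enumerate(f):
            records.append(RuptureRecord(
                traj_id=f"{spec.label or 'sim'}-v{v:g}-r{i}",
                v_pull=v, f_r=float(f_r), peak_x=float("nan")))
    return records


def ca_envelope(spec: CaSeriesSpec, x: np.ndarray) -> np.ndarray:
    """Noiseless planted contact-area curve at elongations ``x`` (nm).

    Each event multiplies the equilibrium mean by a falling sigmoid centred
    at its start elongation with steepness width/10, so the curve passes
    eq_mean/2 at the planted start and is effectively zero one width later.
    """
    env = np.full_like(np.asarray(x, dtype=float), spec.eq_mean)
    for start, width in spec.events:
        env *= 1.0 / (1.0 + np.exp(np.clip((x - start) / (width / 10.0), -500, 500)))
    return env


def gen_ca_series(spec: CaSeriesSpec, seed: int) -> SyntheticCaTrajectory:
    """Equilibrium AR(1) segment plus pulled segment with sigmoidal losses.

    The same AR(1) fluctuation process runs through both segments; in the
    pulled segment its amplitude is scaled by envelope/eq_mean so the noise
    vanishes as the contact is lost.  Values are clamped at zero.
    """
    rng = np.random.default_rng(seed)
    n_pull = int(round(spec.duration / spec.dt)) + 1
    n_total = spec.n_eq + n_pull
    noise = np.empty(n_total)
    stationary_sd = spec.innov_sd / np.sqrt(1.0 - spec.ar_coef ** 2)
    noise[0] = rng.normal(0.0, stationary_sd)
    innovations = rng.normal(0.0, spec.innov_sd, n_total - 1)
    for t in range(1, n_total):
        noise[t] = spec.ar_coef * noise[t - 1] + innovations[t - 1]
    equilibrium = np.clip(spec.eq_mean + noise[:spec.n_eq], 0.0, None)
    x = spec.v_pull * spec.dt * np.arange(n_pull)
    env = ca_envelope(spec, x)
    pulled = np.clip(env + noise[spec.n_eq:] * (env / spec.eq_mean), 0.0, None)
    series = ContactAreaSeries(
        pair_label=spec.label or "synthetic-ca",
        frame_ids=np.arange(n_pull),
        elongation=x,
        ca=pulled,
    )
    return SyntheticCaTrajectory(equilibrium=equilibrium, series=series, spec=spec)


def _rod_model(n_res: int, direction: np.ndarray, spacing: float, origin: np.ndarray,
               chain: str, start_resid: int = 1) -> dict:
    coords = origin[None, :] + spacing * np.arange(n_res)[:, None] * direction[None, :]
    return {
        "names": ["CA"] * n_res,
        "elements": ["C"] * n_res,
        "resids": np.arange(start_resid, start_resid + n_res),
        "resnames": ["ALA"] * n_res,
        "chains": [chain] * n_res,
        "coords": coords,
    }


def sphere_pair(separation: float, element: str = "C") -> StructureModel:
    """Two single-atom 'regions' (chains A and B) at a controlled distance."""
    return StructureModel(
        names=[element, element],
        elements=[element, element],
        resids=np.array([1, 1]),
        resnames=["SPH", "SPH"],
        chains=["A", "B"],
        coords=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
    )


def helix_pair(n_res: int = 20, separation: float = 0.5, rise: float = 0.15,
               offset_b: float = 0.0) -> StructureModel:
    """Two parallel straight Cα rods along x, chains A and B, ``separation``
    nm apart in y; chain B optionally shifted by ``offset_b`` nm in y."""
    x_dir = np.array([1.0, 0.0, 0.0])
    rod_a = _rod_model(n_res, x_dir, rise, np.zeros(3), "A")
    rod_b = _rod_model(n_res, x_dir, rise,
                       np.array([0.0, separation + offset_b, 0.0]), "B")
    return StructureModel(
        names=rod_a["names"] + rod_b["names"],
        elements=rod_a["elements"] + rod_b["elements"],
        resids=np.concatenate([rod_a["resids"], rod_b["resids"]]),
        resnames=rod_a["resnames"] + rod_b["resnames"],
        chains=rod_a["chains"] + rod_b["chains"],
        coords=np.vstack([rod_a["coords"], rod_b["coords"]]),
    )


def helix_pair_frames(n_frames: int, dy_per_frame: float, **kwargs) -> list[StructureModel]:
    """Frame sequence in which chain B translates away by ``dy_per_frame`` nm
    per frame — a monotone contact-area-loss fixture."""
    frames = []
    for i in range(n_frames):
        model = helix_pair(offset_b=i * dy_per_frame, **kwargs)
        model.frame_id = i
        frames.append(model)
    return frames


def tilted_rod(angle_deg: float, n_res: int = 10, rise: float = 0.38) -> StructureModel:
    """Straight Cα rod (chain A, residues 1..n) at ``angle_deg`` to the x-axis.

    With anchors mid=(A,1), n=(A,n_res), c=(A,n_res) the tilt angles both
    equal ``angle_deg`` by construction.
    """
    theta = np.radians(angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    data = _rod_model(n_res, direction, rise, np.zeros(3), "A")
    return StructureModel(**data)


def gen_toy_structure(kind: str, **params) -> StructureModel | list[StructureModel]:
    """Dispatch to the toy-structure builders by kind."""
    builders = {"sphere_pair": sphere_pair, "helix_pair": helix_pair,
                "tilted_rod": tilted_rod, "helix_pair_frames": helix_pair_frames}
    if kind not in builders:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    return builders[kind](**params)


def gen_order_counts(ddg: float, n: int, temperature: float = DEFAULT_TEMPERATURE,
                     seed: int = 0, label_a: str = "A", label_b: str = "B") -> OrderCounts:
    """Binomial first-unfolding counts at barrier difference ``ddg`` (kcal/mol)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    p = p_from_ddg(ddg, temperature)
    k = int(rng.binomial(n, p))
    return OrderCounts(n=n, k=k, label_a=label_a, label_b=label_b,
                       temperature=temperature)
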