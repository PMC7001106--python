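"""Overdamped (Brownian) Langevin dynamics in the membrane plane.

The desk-scale surrogate for coarse-grained membrane MD: lipid head
particles diffuse laterally in a periodic box under planted site wells,
the protein-footprint wall, and optional harmonic biases, via the
Euler-Maruyama update

    x <- x + (D / k_B T) F(x) dt + sqrt(2 D dt) eta,

with eta standard normal per component.  Only the sampled
configurations matter for the downstream analyses, not force-field
detail, so a single free diffusion coefficient D stands in for lipid
mobility.

Coordinates are integrated and stored unwrapped; periodic wrapping is
applied inside force terms and distance computations only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import MembraneSystem, Trajectory
from .potentials import GaussianWell, system_force_function
from .units import kBT

__all__ = ["DynamicsParams", "SimulationError", "simulate", "brownian_integrate"]


class SimulationError(RuntimeError):
    """Non-finite forces/coordinates; message carries the step index."""


@dataclass
class DynamicsParams:
    """Parameters of the Brownian integrator.

    D is a surrogate mobility (nm^2/ns), not a physical claim about any
    particular lipid; dt is the integration step (ns).  The default
    dt = 0.01 ns keeps the per-step RMS displacement sqrt(2 D dt) well
    below typical well widths; stiffly biased protocols use a smaller
    step (see the umbrella and alchemy modules).
    """

    D: float = 0.1  # nm^2/ns
    dt: float = 0.01  # ns
    temperature: float = 310.0  # K
    n_steps: int = 10_000
    save_every: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or self.dt <= 0 or self.temperature <= 0:
            raise ValueError("require D >= 0, dt > 0, temperature > 0")
        if self.n_steps < 1 or self.save_every < 1:
            raise ValueError("n_steps and save_every must be >= 1")

    @property
    def rms_step(self) -> float:
        """Per-step RMS random displacement per component, nm."""
        return float(np.sqrt(2.0 * self.D * self.dt))

    def check_stability(self, wells: Sequence[GaussianWell]) -> None:
        """Per-step RMS displacement must stay below sigma/3 of the
        narrowest well, or the integrator cannot resolve it."""
        sigmas = [w.sigma for w in wells if isinstance(w, GaussianWell)]
        if sigmas and self.rms_step >= min(sigmas) / 3.0:
            raise ValueError(
                f"unstable dynamics: rms step {self.rms_step:.4f} nm >= "
                f"sigma/3 = {min(sigmas) / 3.0:.4f} nm of the narrowest well; "
                "reduce dt or D"
            )


def brownian_integrate(
    x0: np.ndarray,
    force_fn: Callable[[np.ndarray], np.ndarray],
    D: float,
    temperature: float,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    record_every: int = 1,
    record_first: bool = False,
    mobile: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate and record positions.

    ``x0`` may carry arbitrary leading dimensions (e.g. one row per
    umbrella window integrated simultaneously); the trailing dimension
    is the 2D plane.  Returns an array (n_recorded, *x0.shape).
    """
    x = np.array(x0, dtype=float)
    beta_D_dt = D * dt / kBT(temperature)
    noise_scale = np.sqrt(2.0 * D * dt)
    n_rec = n_steps // record_every + (1 if record_first else 0)
    out = np.empty((n_rec, *x.shape))
    rec = 0
    if record_first:
        out[rec] = x
        rec += 1
    for step in range(1, n_steps + 1):
        f = force_fn(x)
        dx = beta_D_dt * f + noise_scale * rng.standard_normal(x.shape)
        if mobile is not None:
            dx[~mobile] = 0.0
        x += dx
        if step % record_every == 0:
            if not np.all(np.isfinite(x)):
                raise SimulationError(
                    f"non-finite coordinates at step {step} "
                    "(particle at a singular point or unstable parameters)"
                )
            out[rec] = x
            rec += 1
    return out


def simulate(
    system: MembraneSystem,
    potentials: Sequence,
    params: DynamicsParams,
    biases: Sequence = (),
) -> Trajectory:
    """Run Brownian dynamics for every mobile particle of a system.

    The trajectory contains the initial configuration plus one frame
    every ``save_every`` steps; identical (system, potentials, params)
    give a bit-identical trajectory.  Protein and site-anchor particles
    never move.  z coordinates are carried through unchanged (leaflets
    keep their level; the dynamics is in-plane).
    """
    terms = list(potentials) + list(biases)
    params.check_stability(terms)
    force_fn = system_force_function(system, terms)
    mobile = system.mobile_mask()
    rng = np.random.default_rng(params.seed)

    xy = brownian_integrate(
        system.coordinates[:, :2],
        force_fn,
        D=params.D,
        temperature=params.temperature,
        dt=params.dt,
        n_steps=params.n_steps,
        rng=rng,
        record_every=params.save_every,
        record_first=True,
        mobile=mobile,
    )
    n_frames = xy.shape[0]
    coords = np.empty((n_frames, system.n_particles, 3))
    coords[:, :, :2] = xy
    coords[:, :, 2] = system.coordinates[:, 2]
    times = np.arange(n_frames) * params.save_every * params.dt
    return Trajectory(system=system, times=times, coords=coords)
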