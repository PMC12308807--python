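"""Seeded synthetic data with the statistical structure the method assumes.

Molecular trajectories of small peptides are, for the embedding method's
purposes, point clouds with a few well-separated metastable basins plus
thermal noise, visited by a correlated sampler.  Three generators emulate
exactly that, so the whole pipeline is testable without any simulation
data:

* a Gaussian mixture in feature space (metastable basins with known
  ground-truth labels),
* a Metropolis-sampled double-well angle trajectory (a two-state torsion
  with a prescribed free-energy barrier, including the time correlation
  characteristic of MD),
* random chain "conformations" with unit bonds and known torsions
  (exercises the featurizer end to end).

All generators are bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np

from .features import ConformationSet

__all__ = [
    "make_gaussian_mixture",
    "make_double_well_angles",
    "double_well_potential",
    "make_toy_conformations",
]


def _rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def make_gaussian_mixture(
    n_clusters: int = 3,
    dim: int = 10,
    n_per_cluster: int = 100,
    separation: float = 8.0,
    random_state=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic unit-variance Gaussian clusters at mutually orthogonal means.

    Cluster ``c`` is centered at ``separation * e_c`` (the c-th coordinate
    unit vector), so all pairs of centers are ``separation * sqrt(2)``
    apart.  Labels are returned for evaluation only; the embedding never
    sees them.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if dim < n_clusters:
        raise ValueError(
            f"dim ({dim}) must be >= n_clusters ({n_clusters}) for "
            "orthogonal cluster means"
        )
    rng = _rng(random_state)
    X = rng.standard_normal((n_clusters * n_per_cluster, dim))
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    for c in range(n_clusters):
        X[labels == c, c] += separation
    return X, labels


def double_well_potential(theta_deg, barrier: float = 6.0) -> np.ndarray:
    """Periodic double-well potential ``U = barrier * sin^2(theta)`` (kJ/mol).

    Minima at 0 and 180 degrees, maxima of height ``barrier`` at +/-90.
    """
    return barrier * np.sin(np.radians(np.asarray(theta_deg, dtype=float))) ** 2


def make_double_well_angles(
    n: int = 100_000,
    barrier: float = 6.0,
    kT: float = 2.494,
    step_deg: float = 60.0,
    burn_in: int = 1000,
    thin: int = 10,
    random_state=None,
) -> np.ndarray:
    """Metropolis trajectory on the double-well torsion potential.

    Samples the stationary density ``exp(-U(theta)/kT)`` on the circle with
    a wrapped Gaussian proposal of ``step_deg`` degrees.  Metropolis (rather
    than exact inversion) is used deliberately: the output is a *correlated*
    trajectory, like an MD torsion trace.  ``kT = 2.494`` kJ/mol corresponds
    to 300 K.

    Returns ``n`` angles in degrees in (-180, 180], recorded every ``thin``
    steps after ``burn_in`` equilibration steps.
    """
    if barrier <= 0 or kT <= 0:
        raise ValueError("barrier and kT must be positive")
    if n < 1 or thin < 1 or burn_in < 0:
        raise ValueError("invalid n / thin / burn_in")
    rng = _rng(random_state)
    total = burn_in + n * thin
    proposals = rng.normal(0.0, step_deg, size=total)
    accepts = rng.random(total)
    beta = 1.0 / kT
    out = np.empty(n)
    theta = 0.0
    u = 0.0  # U(0) = 0
    k = 0
    sin, log = math.sin, math.log
    rad = math.pi / 180.0
    for t in range(total):
        cand = theta + proposals[t]
        # wrap into (-180, 180]
        cand = cand - 360.0 * math.floor((cand + 180.0) / 360.0)
        if cand <= -180.0:
            cand += 360.0
        s = sin(cand * rad)
        u_cand = barrier * s * s
        if u_cand <= u or accepts[t] < math.exp(-beta * (u_cand - u)):
            theta, u = cand, u_cand
        if t >= burn_in and (t - burn_in) % thin == thin - 1:
            out[k] = theta
            k += 1
    return out


def make_toy_conformations(
    n_frames: int = 10,
    n_atoms: int = 8,
    bond_angle_deg: float = 109.47,
    random_state=None,
) -> tuple[ConformationSet, np.ndarray]:
    """Random chain molecules with unit bonds and known torsions.

    Atoms are placed by the natural extension reference frame: every atom
    beyond the third is positioned at unit bond length, fixed bond angle,
    and a torsion drawn uniformly from (-180, 180].  Element labels
    alternate C/H so heavy-atom selection is exercised.

    Returns the conformations and the (n_frames, n_atoms - 3) torsions
    actually used, so torsion analysis can be round-trip checked.
    """
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms for a torsion")
    rng = _rng(random_state)
    torsions = rng.uniform(-180.0, 180.0, size=(n_frames, n_atoms - 3))
    theta = math.radians(bond_angle_deg)
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        p = coords[f]
        p[0] = (0.0, 0.0, 0.0)
        p[1] = (1.0, 0.0, 0.0)
        p[2] = p[1] + (math.cos(math.pi - theta), math.sin(math.pi - theta), 0.0)
        for a in range(3, n_atoms):
            p[a] = _nerf_place(p[a - 3], p[a - 2], p[a - 1], 1.0, theta,
                               math.radians(torsions[f, a - 3]))
    labels = ["C" if i % 2 == 0 else "H" for i in range(n_atoms)]
    return ConformationSet(coords, labels), torsions


def _nerf_place(A, B, C, r: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms A, B, C."""
    b1 = B - A
    b2 = C - B
    b2_hat = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, b2_hat)
    d_local = np.array([
        -r * math.cos(bond_angle),
        r * math.sin(bond_angle) * math.cos(torsion),
        r * math.sin(bond_angle) * math.sin(torsion),
    ])
    return C + d_local[0] * b2_hat + d_local[1] * m_hat + d_local[2] * n_hat
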