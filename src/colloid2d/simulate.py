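"""Ground-truth point-process simulators and a synthetic AFM image renderer.

Three generating regimes mirror the phenomenology of adsorbed colloids:

* **CSR** — independent uniform positions (non-interacting particles, the
  Poisson reference).
* **Hard core** — sequential random placement with a strict minimum-approach
  distance R (dart throwing / random sequential adsorption), the idealised
  limit of strong short-range repulsion; counts are sub-Poisson.
* **Soft repulsive** — Metropolis Monte Carlo equilibrium of particles with
  a truncated Lennard-Jones core plus screened-Coulomb (Yukawa) repulsion
  in a periodic box, reproducing the amorphous short-range order (exclusion
  zone + first-shell peak) seen for charged nanoparticles.  Monte Carlo is
  used deliberately: g(r) probes equilibrium structure, not dynamics, and a
  screened tail keeps the truncation well defined under periodic boundaries.
* **Cluster** — a Thomas (Neyman–Scott) process: uniform parents with
  Gaussian-scattered offspring; counts are super-Poisson.

The renderer paints each particle as a Gaussian bump of given height and
width onto a pixel grid and adds white measurement noise, emulating AFM
scans of compact objects on flat mica (protein-sized bumps ~1–2 nm tall, or
nanoparticle bumps ~15 nm, over a noise floor well below 0.5 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import HeightMap, PointPattern, ValidationError


@dataclass(frozen=True)
class Repulsion:
    """Pair-potential parameters for the soft-repulsive process.

    U(d) = 4ε[(σ/d)¹² − (σ/d)⁶] + ε_c · exp(−κ d)/d, truncated at ``cutoff``.
    Energies are in reduced units (k_B T = 1 at temperature 1).
    """

    epsilon: float = 1.0
    coulomb: float = 0.0
    kappa: float = 0.01
    lj_sigma: float = 100.0
    cutoff: float = 1000.0


@dataclass(frozen=True)
class MCParams:
    """Metropolis sampler controls: sweeps, reduced temperature, step size."""

    n_sweeps: int = 200
    temperature: float = 1.0
    max_step: float = 100.0


@dataclass(frozen=True)
class ClusterParams:
    """Thomas-process controls: parents and Gaussian offspring scatter."""

    n_parents: int = 20
    offspring_per_parent_mean: float = 50.0
    offspring_sd: float = 200.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic point pattern."""

    window: tuple[float, float] = (10_000.0, 10_000.0)
    n_points: int = 1000
    process: str = "csr"
    hardcore_radius: float = 0.0
    repulsion: Repulsion = field(default_factory=Repulsion)
    mc: MCParams = field(default_factory=MCParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValidationError("window sides must be positive")
        if self.n_points < 0:
            raise ValidationError("n_points must be >= 0")
        if self.hardcore_radius < 0:
            raise ValidationError("hardcore_radius must be >= 0")


@dataclass(frozen=True)
class RenderConfig:
    """Synthetic AFM image parameters (heights in nm)."""

    pixel_size: float = 20.0
    bump_height: float = 2.0
    bump_sigma: float = 30.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and self.bump_sigma > 0):
            raise ValidationError("pixel_size and bump_sigma must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate(config: SimConfig) -> PointPattern:
    """Dispatch on ``config.process``."""
    dispatch = {
        "csr": simulate_csr,
        "hardcore": simulate_hardcore,
        "soft_repulsive": simulate_soft_repulsive,
        "cluster": simulate_cluster,
    }
    if config.process not in dispatch:
        raise ValidationError(f"unknown process {config.process!r}")
    return dispatch[config.process](config)


def simulate_csr(config: SimConfig) -> PointPattern:
    """Homogeneous binomial pattern: n_points iid uniform positions."""
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    pts = rng.uniform(0, [w, h], size=(config.n_points, 2))
    return PointPattern(points=pts, window=config.window)


def _min_image_sq(p: np.ndarray, q: np.ndarray, w: float, h: float) -> np.ndarray:
    dx = np.abs(p[..., 0] - q[..., 0])
    dy = np.abs(p[..., 1] - q[..., 1])
    dx = np.minimum(dx, w - dx)
    dy = np.minimum(dy, h - dy)
    return dx * dx + dy * dy


def simulate_hardcore(config: SimConfig) -> PointPattern:
    """Sequential hard-core placement with periodic minimum-image distances.

    Uniform proposals are accepted only if at least ``hardcore_radius`` from
    every previously accepted point, so the minimum pairwise distance is
    ≥ R exactly.  If the requested packing is infeasible (disc coverage
    n·πR² above ~30% of the window, or proposals exhausted) the achievable
    pattern is returned with a warning.
    """
    R = config.hardcore_radius
    if R <= 0:
        raise ValidationError("hardcore_radius must be positive")
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    target = config.n_points

    # cell list with cell edge >= R: only 3x3 neighbourhoods need checking
    nx = max(1, int(w // R))
    ny = max(1, int(h // R))
    cells: dict[tuple[int, int], list[np.ndarray]] = {}
    accepted: list[np.ndarray] = []
    r2 = R * R
    max_attempts = max(200 * max(target, 1), 10_000)
    attempts = 0
    while len(accepted) < target and attempts < max_attempts:
        attempts += 1
        p = rng.uniform(0, [w, h])
        cx, cy = int(p[0] / w * nx), int(p[1] / h * ny)
        cx, cy = min(cx, nx - 1), min(cy, ny - 1)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for q in cells.get(((cx + dx) % nx, (cy + dy) % ny), ()):
                    if _min_image_sq(p, q, w, h) < r2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(p)
            cells.setdefault((cx, cy), []).append(p)
    if len(accepted) < target:
        warnings.warn(
            f"hard-core packing infeasible: placed {len(accepted)} of "
            f"{target} points at R = {R} nm", stacklevel=2)
    pts = np.array(accepted, dtype=float).reshape(-1, 2)
    return PointPattern(points=pts, window=config.window)


def _pair_energy(d: np.ndarray, rep: Repulsion) -> np.ndarray:
    """Truncated LJ + Yukawa pair energy; zero beyond the cutoff."""
    d = np.asarray(d, dtype=float)
    inside = (d > 0) & (d < rep.cutoff)
    u = np.zeros_like(d)
    if np.any(inside):
        dd = d[inside]
        e = np.zeros_like(dd)
        if rep.epsilon != 0.0:
            s6 = (rep.lj_sigma / dd) ** 6
            e = e + 4.0 * rep.epsilon * (s6 * s6 - s6)
        if rep.coulomb != 0.0:
            e = e + rep.coulomb * np.exp(-rep.kappa * dd) / dd
        u[inside] = e
    return u


def simulate_soft_repulsive(config: SimConfig) -> PointPattern:
    """Metropolis Monte Carlo of soft-core repulsive particles.

    Starts from CSR, auto-jitters exact overlaps, tunes the single-particle
    step toward ~30–50% acceptance during the first half of the run, and
    returns the configuration after ``mc.n_sweeps`` sweeps.  The acceptance
    rate over the post-tuning sweeps is available afterwards from
    :func:`last_acceptance_rate`.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    rep = config.repulsion
    if rep.cutoff > min(w, h) / 2:
        raise ValidationError("cutoff must not exceed half the shorter window side")
    n = config.n_points
    pts = rng.uniform(0, [w, h], size=(n, 2))
    if n < 2:
        return PointPattern(points=pts, window=config.window)

    # jitter coincident points so the LJ core cannot diverge at d = 0
    d2 = _min_image_sq(pts[:, None, :], pts[None, :, :], w, h)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < 1e-12:
        pts += rng.normal(scale=1e-3 * rep.lj_sigma, size=pts.shape)
        pts %= [w, h]

    temp = config.mc.temperature
    step = config.mc.max_step
    accepted = 0
    proposed = 0
    tune_until = config.mc.n_sweeps // 2
    for sweep in range(config.mc.n_sweeps):
        order = rng.permutation(n)
        moves = rng.uniform(-step, step, size=(n, 2))
        us = rng.random(n)
        for k, i in enumerate(order):
            old = pts[i].copy()
            new = (old + moves[k]) % [w, h]
            others = np.delete(np.arange(n), i)
            d_old = np.sqrt(_min_image_sq(old, pts[others], w, h))
            d_new = np.sqrt(_min_image_sq(new, pts[others], w, h))
            delta = _pair_energy(d_new, rep).sum() - _pair_energy(d_old, rep).sum()
            proposed += 1
            if delta <= 0 or us[k] < np.exp(-delta / temp):
                pts[i] = new
                accepted += 1
        if sweep < tune_until and (sweep + 1) % 10 == 0 and proposed:
            rate = accepted / proposed
            if rate < 0.3:
                step = max(step * 0.8, 1e-3)
            elif rate > 0.5:
                step = min(step * 1.25, min(w, h) / 4)
            accepted = proposed = 0
    global _LAST_ACCEPTANCE
    _LAST_ACCEPTANCE = accepted / proposed if proposed else float("nan")
    return PointPattern(points=pts, window=config.window)


_LAST_ACCEPTANCE: float = float("nan")


def last_acceptance_rate() -> float:
    """Acceptance rate of the most recent soft-repulsive run (post-tuning)."""
    return _LAST_ACCEPTANCE


def simulate_cluster(config: SimConfig) -> PointPattern:
    """Thomas process: uniform parents, Gaussian offspring, periodic wrap.

    Offspring counts are Poisson with the configured mean, so the expected
    total is n_parents × offspring mean; daughter positions are wrapped
    into the window to keep the intensity homogeneous.
    """
    cl = config.cluster
    if cl.n_parents < 1:
        raise ValidationError("n_parents must be >= 1")
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    parents = rng.uniform(0, [w, h], size=(cl.n_parents, 2))
    counts = rng.poisson(cl.offspring_per_parent_mean, size=cl.n_parents)
    reps = np.repeat(np.arange(cl.n_parents), counts)
    offspring = parents[reps] + rng.normal(scale=cl.offspring_sd,
                                           size=(reps.size, 2))
    offspring %= [w, h]
    return PointPattern(points=offspring.reshape(-1, 2), window=config.window)


def render_afm_image(pattern: PointPattern, config: RenderConfig) -> HeightMap:
    """Render a point pattern as a synthetic AFM height map.

    Each particle contributes a Gaussian bump
    ``height · exp(−d²/(2σ²))`` centred at its position (per-particle
    heights from ``pattern.heights`` when present, else the global
    ``bump_height``), plus iid Gaussian pixel noise.  Pixel (row i, col j)
    has its centre at ``(j·pixel_size, i·pixel_size)``.
    """
    w, h = pattern.window
    cols = max(1, int(round(w / config.pixel_size)))
    rows = max(1, int(round(h / config.pixel_size)))
    img = np.zeros((rows, cols))
    sigma_px = config.bump_sigma / config.pixel_size
    half = max(1, int(np.ceil(4 * sigma_px)))
    if pattern.heights is not None:
        amps = np.asarray(pattern.heights, dtype=float)
    else:
        amps = np.full(pattern.n, config.bump_height)
    for (x, y), amp in zip(pattern.points, amps):
        cx, cy = x / config.pixel_size, y / config.pixel_size
        j0, j1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        i0, i1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        j0c, j1c = max(j0, 0), min(j1, cols)
        i0c, i1c = max(i0, 0), min(i1, rows)
        if j0c >= j1c or i0c >= i1c:
            continue
        jj = np.arange(j0c, j1c)
        ii = np.arange(i0c, i1c)
        gx = np.exp(-((jj - cx) ** 2) / (2 * sigma_px ** 2))
        gy = np.exp(-((ii - cy) ** 2) / (2 * sigma_px ** 2))
        img[i0c:i1c, j0c:j1c] += amp * gy[:, None] * gx[None, :]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        img += rng.normal(scale=config.noise_sd, size=img.shape)
    return HeightMap(img, config.pixel_size)


def fig1_like(process: str = "soft_repulsive", seed: int = 0) -> SimConfig:
    """Preset qualitatively matching the repulsive-monolayer phenomenology:
    an exclusion zone followed by a first-shell peak in g(r) and sub-Poisson
    quadrat counts, at nanoparticle-like densities."""
    return SimConfig(
        window=(10_000.0, 10_000.0),
        n_points=400,
        process=process,
        hardcore_radius=350.0,
        repulsion=Repulsion(epsilon=1.0, coulomb=2000.0, kappa=0.004,
                            lj_sigma=250.0, cutoff=2500.0),
        mc=MCParams(n_sweeps=300, temperature=1.0, max_step=150.0),
        cluster=ClusterParams(n_parents=20, offspring_per_parent_mean=20.0,
                              offspring_sd=300.0),
        seed=seed,
    )
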