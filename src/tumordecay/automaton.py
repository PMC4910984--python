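"""Two-phase cellular automaton: avascular tumor growth, then immune lysis.

Phase 1 grows a tumor from a single seed on an ``n x n`` lattice fed by two
vessel columns on the vertical sides.  Nutrients diffuse from the vessels
and are consumed by the tissue; division probability depends on the local
division nutrient, so the consumption parameters ``alpha`` (overall) and
``lambda_N`` (tumor excess) select the morphology: weak consumption gives a
compact ("spherical") tumor, strong consumption a branched papillary or
filamentary one.

Phase 2 freezes the tumor (as if irradiated), inscribes it in its
circumscribing circle, fills an angular sector ``gamma`` of the remaining
circle with immune cells, and iterates probabilistic immune actions — lyse,
recruit, inactivate — one sweep per hour until the tumor is eradicated.
Immune cells far from the tumor inactivate within the first steps, so what
survives is the layer of effectors wrapping the tumor: the automaton
realization of the surface-erosion limit of the fractional cell kill.

Cell states: 0 = healthy, 1 = tumor, 2 = immune.  One automaton step is one
hour (one lysis takes an effector about an hour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.sparse.linalg import LinearOperator, cg

from .series import LysisSeries

__all__ = [
    "HEALTHY",
    "TUMOR",
    "IMMUNE",
    "CAConfig",
    "CAGrid",
    "NutrientField",
    "GrowthStallError",
    "preset_config",
    "MORPHOLOGY_PRESETS",
    "solve_nutrients",
    "grow_tumor",
    "place_immune_cells",
    "run_lysis",
    "run_experiment",
    "erode_ball_3d",
    "morphology_metrics",
]

HEALTHY, TUMOR, IMMUNE = 0, 1, 2

_VN = ((-1, 0), (1, 0), (0, -1), (0, 1))
_MOORE = _VN + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class GrowthStallError(RuntimeError):
    """Raised when the growth phase cannot reach the target size."""

    def __init__(self, step: int, tumor_count: int, message: str | None = None):
        self.step = step
        self.tumor_count = tumor_count
        super().__init__(
            message
            or f"tumor growth stalled at step {step} with {tumor_count} cells"
        )


@dataclass(frozen=True)
class CAConfig:
    """Automaton parameters.

    Nutrient parameters: ``alpha`` is the baseline consumption factor per
    grid unit (e.g. 2/n; the healthy-tissue nutrient decay length is
    1/alpha lattice units), ``lambda_N``/``lambda_M`` scale the tumor's
    excess consumption of the division (N) and maintenance (M) nutrient.

    Action parameters ``theta_*`` steer the probabilistic rules (see
    docs/methods.md for the exact forms).  Sentinels: ``theta_div = 0`` and
    ``theta_mig = inf`` disable division/migration; ``theta_nec = 0``
    disables necrosis.  ``max_lyses`` is the number of kills an immune cell
    delivers before it is spent (3).
    """

    n: int
    alpha: float
    lambda_N: float
    lambda_M: float = 10.0
    theta_div: float = 0.3
    theta_mig: float = math.inf
    theta_nec: float = 0.0
    theta_lys: float = 0.3
    theta_rec: float = 0.5
    theta_inc: float = 0.5
    max_lyses: int = 3
    target_size: int = 9100
    seed: int = 0
    nutrient_boundary: float = 1.0
    nutrient_scale: float = 250.0
    nutrient_update_every: int = 3
    nutrient_rtol: float = 1e-4
    recruit_neighborhood: str = "moore"
    step_cap_factor: int = 10
    max_growth_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for name in ("theta_div", "theta_mig", "theta_nec", "theta_lys", "theta_rec", "theta_inc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_lyses < 1:
            raise ValueError("max_lyses must be >= 1")
        if not 0 < self.target_size <= self.n**2:
            raise ValueError("target_size must be in (0, n^2]")
        if self.recruit_neighborhood not in ("moore", "von_neumann"):
            raise ValueError("recruit_neighborhood must be 'moore' or 'von_neumann'")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # noqa: SLF001 - dataclass introspection
        }
        if math.isinf(d["theta_mig"]):
            d["theta_mig"] = "inf"
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "CAConfig":
        m = dict(mapping)
        if m.get("theta_mig") in ("inf", ".inf"):
            m["theta_mig"] = math.inf
        return cls(**m)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CAConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Fig-6-style morphology presets: (alpha multiplier over 1/n, lambda_N).
#: All share lambda_M = 10, theta_div = 0.3, necrosis and migration off.
MORPHOLOGY_PRESETS = {
    "spherical": (2.0, 25.0),
    "papillary": (4.0, 200.0),
    "filamentary": (8.0, 270.0),
}


def preset_config(
    name: str,
    n: int = 300,
    target_size: int = 9100,
    seed: int = 0,
    **overrides,
) -> CAConfig:
    """Build the configuration for a named morphology preset."""
    try:
        mult, lam_n = MORPHOLOGY_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(MORPHOLOGY_PRESETS)}"
        ) from None
    cfg = CAConfig(n=n, alpha=mult / n, lambda_N=lam_n, target_size=target_size, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class CAGrid:
    """Lattice state plus per-immune-cell lysis counters.

    Vessels occupy the first and last columns (Dirichlet nutrient boundary);
    they are not cell sites that tumors normally reach at the sizes used.
    """

    state: np.ndarray
    lysis_count: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.ndim != 2 or self.state.shape[0] != self.state.shape[1]:
            raise ValueError("state must be a square 2-D array")
        if self.lysis_count is None:
            self.lysis_count = np.zeros_like(self.state, dtype=np.int16)
        else:
            self.lysis_count = np.asarray(self.lysis_count, dtype=np.int16)
            if self.lysis_count.shape != self.state.shape:
                raise ValueError("lysis_count shape mismatch")

    @property
    def n(self) -> int:
        return self.state.shape[0]

    def counts(self) -> dict:
        return {
            "healthy": int(np.sum(self.state == HEALTHY)),
            "tumor": int(np.sum(self.state == TUMOR)),
            "immune": int(np.sum(self.state == IMMUNE)),
        }

    def tumor_mask(self) -> np.ndarray:
        return self.state == TUMOR

    def copy(self) -> "CAGrid":
        return CAGrid(self.state.copy(), self.lysis_count.copy(), dict(self.meta))

    def to_text(self, path) -> None:
        np.savetxt(path, self.state, fmt="%d", header=f"n={self.n}")

    @classmethod
    def from_text(cls, path) -> "CAGrid":
        return cls(np.loadtxt(path, dtype=np.int8))


@dataclass
class NutrientField:
    """Steady-state division (N) and maintenance (M) nutrient fields."""

    N: np.ndarray
    M: np.ndarray


class _NutrientSolver:
    """Preconditioned CG solver for the steady reaction-diffusion equation.

    Solves laplacian(u) = k(site) * u on the interior columns with u fixed
    at the boundary value on the two vessel columns and periodic wrap
    vertically.  The operator (4 + k) u - sum(neighbors) is symmetric
    positive definite; it is preconditioned with the exact inverse of its
    spatial mean (FFT along the periodic axis x DST-I along the Dirichlet
    axis diagonalizes the constant-coefficient part), so conjugate
    gradients converge in a handful of iterations at any grid size.
    """

    def __init__(self, n: int, boundary: float = 1.0):
        self.n = n
        self.m = n - 2
        self.boundary = boundary
        rhs = np.zeros((n, self.m))
        rhs[:, 0] += boundary
        rhs[:, -1] += boundary
        self._rhs = rhs.ravel()
        lam_y = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n // 2 + 1) / n)
        lam_x = 2.0 - 2.0 * np.cos(np.pi * np.arange(1, self.m + 1) / (self.m + 1))
        self._eig = lam_y[:, None] + lam_x[None, :]

    def _precondition(self, r: np.ndarray, kbar: float) -> np.ndarray:
        from scipy import fft as sfft

        R = r.reshape(self.n, self.m)
        t = sfft.dst(R, type=1, axis=1, norm="ortho")
        t = sfft.rfft(t, axis=0)
        t /= self._eig + kbar
        t = sfft.irfft(t, n=self.n, axis=0)
        return sfft.idst(t, type=1, axis=1, norm="ortho").ravel()

    def solve(self, k: np.ndarray, x0: np.ndarray | None = None, rtol: float = 1e-6) -> np.ndarray:
        n, m = self.n, self.m
        kbar = float(k.mean())

        def matvec(v):
            V = v.reshape(n, m)
            out = (4.0 + k) * V
            out -= np.roll(V, 1, axis=0)
            out -= np.roll(V, -1, axis=0)
            out[:, 1:] -= V[:, :-1]
            out[:, :-1] -= V[:, 1:]
            return out.ravel()

        A = LinearOperator((n * m, n * m), matvec=matvec, dtype=float)
        M = LinearOperator(
            (n * m, n * m), matvec=lambda r: self._precondition(r, kbar), dtype=float
        )
        x0v = np.full(n * m, self.boundary) if x0 is None else x0.ravel()
        x, info = cg(A, self._rhs, x0=x0v, M=M, rtol=rtol, atol=0.0, maxiter=50 * n)
        if info != 0:
            raise RuntimeError(f"nutrient solver did not converge (info={info})")
        full = np.empty((n, n))
        full[:, 0] = self.boundary
        full[:, -1] = self.boundary
        full[:, 1:-1] = np.maximum(x.reshape(n, m), 0.0)
        return full


def _consumption(state: np.ndarray, base: float, tumor: float) -> np.ndarray:
    """Interior consumption coefficients: ``base`` per site, ``tumor`` on
    tumor sites."""
    k = np.full(state.shape, base, dtype=float)
    k[state == TUMOR] = tumor
    return k[:, 1:-1]


def _division_consumption(config: CAConfig) -> float:
    """Tumor consumption coefficient of the division nutrient N.

    The relative factor lambda_N * alpha (the knob that selects the
    morphology) is normalized by the lattice scale ``nutrient_scale / n^2``;
    the resulting depletion length 1/sqrt(k) sets the branch thickness.
    Quiescent healthy tissue does not draw on the proliferation substrate.
    """
    return config.nutrient_scale * config.lambda_N * config.alpha / config.n**2


def _maintenance_consumption(config: CAConfig) -> tuple[float, float]:
    """(healthy, tumor) consumption coefficients of the maintenance
    nutrient M: all tissue consumes, tumor lambda_M-fold faster."""
    return config.alpha**2, config.lambda_M * config.alpha**2


def solve_nutrients(grid: CAGrid, config: CAConfig) -> NutrientField:
    """Steady-state nutrient fields for the current lattice occupancy.

    The division nutrient N is consumed by proliferating tumor sites only
    (coefficient lambda_N * alpha normalized by the lattice scale, see
    :func:`_division_consumption`); the maintenance nutrient M by all
    tissue, at alpha^2 * u on healthy/immune sites and lambda_M * alpha^2
    on tumor.  Vessel columns hold the Dirichlet value; the vertical
    direction is periodic.
    """
    if grid.n != config.n:
        raise ValueError("grid size does not match config.n")
    solver = _NutrientSolver(config.n, config.nutrient_boundary)
    n_field = solver.solve(
        _consumption(grid.state, 0.0, _division_consumption(config)),
        rtol=config.nutrient_rtol,
    )
    m_base, m_tumor = _maintenance_consumption(config)
    m_field = solver.solve(
        _consumption(grid.state, m_base, m_tumor), rtol=config.nutrient_rtol
    )
    return NutrientField(N=n_field, M=m_field)


def _constant_drive_prob(theta: float) -> float:
    """P = 1 - exp(-1/theta^2) for the constant-drive actions."""
    if theta == 0:
        return 1.0
    if math.isinf(theta):
        return 0.0
    return 1.0 - math.exp(-1.0 / theta**2)


def _neighbor_any(mask: np.ndarray, offsets) -> np.ndarray:
    """Sites having at least one True neighbor under the given offsets.

    Vertical wrap is periodic (matching the nutrient boundary conditions);
    horizontal shifts do not wrap across the vessel columns.
    """
    out = np.zeros_like(mask)
    for dy, dx in offsets:
        shifted = np.roll(mask, dy, axis=0)
        if dx > 0:
            out[:, dx:] |= shifted[:, :-dx]
        elif dx < 0:
            out[:, :dx] |= shifted[:, -dx:]
        else:
            out |= shifted
    return out


def _free_neighbors(state: np.ndarray, y: int, x: int, offsets, value: int):
    n = state.shape[0]
    out = []
    for dy, dx in offsets:
        yy, xx = (y + dy) % n, x + dx
        if 0 <= xx < n and state[yy, xx] == value:
            out.append((yy, xx))
    return out


def grow_tumor(config: CAConfig, rng: np.random.Generator | None = None) -> CAGrid:
    """Phase 1: grow a tumor from a central seed up to ``target_size`` cells.

    Per step (hour): re-solve the division nutrient field, then sweep the
    tumor cells bordering healthy tissue in random order; each divides with
    probability 1 - exp(-(N/theta_div)^2) into a uniformly chosen healthy
    von Neumann neighbor.  Necrosis (theta_nec > 0) and migration
    (theta_mig < inf) follow the same sweep pattern but are disabled in all
    morphology presets.  Stops at the first step where the tumor count
    reaches the target; raises :class:`GrowthStallError` if no division is
    possible.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    state = np.zeros((n, n), dtype=np.int8)
    center = n // 2
    state[center, center] = TUMOR
    tumor_count = 1
    if config.target_size <= 1:
        return CAGrid(state, meta={"steps": 0, "config": config.to_dict()})

    solver = _NutrientSolver(n, config.nutrient_boundary)
    n_interior = None
    m_interior = None
    p_mig = _constant_drive_prob(config.theta_mig) if config.theta_mig > 0 else 0.0
    use_necrosis = config.theta_nec > 0

    for step in range(1, config.max_growth_steps + 1):
        if step % config.nutrient_update_every == 1 or config.nutrient_update_every == 1:
            n_interior = solver.solve(
                _consumption(state, 0.0, _division_consumption(config)),
                x0=n_interior,
                rtol=config.nutrient_rtol,
            )[:, 1:-1]
            if use_necrosis:
                m_base, m_tumor = _maintenance_consumption(config)
                m_interior = solver.solve(
                    _consumption(state, m_base, m_tumor),
                    x0=m_interior,
                    rtol=config.nutrient_rtol,
                )[:, 1:-1]
        n_full = np.empty((n, n))
        n_full[:, 0] = n_full[:, -1] = config.nutrient_boundary
        n_full[:, 1:-1] = n_interior

        tumor = state == TUMOR
        can_divide = tumor & _neighbor_any(state == HEALTHY, _VN)
        ys, xs = np.nonzero(can_divide)
        if len(ys) == 0 and tumor_count < config.target_size:
            raise GrowthStallError(step, tumor_count)
        if config.theta_div == 0:
            raise GrowthStallError(step, tumor_count, "division disabled (theta_div = 0)")
        p_div = 1.0 - np.exp(-((n_full[ys, xs] / config.theta_div) ** 2))
        success = rng.random(len(ys)) < p_div
        order = rng.permutation(np.flatnonzero(success))
        for i in order:
            free = _free_neighbors(state, ys[i], xs[i], _VN, HEALTHY)
            if not free:
                continue
            ty, tx = free[rng.integers(len(free))]
            state[ty, tx] = TUMOR
            tumor_count += 1
            if tumor_count >= config.target_size:
                break

        if p_mig > 0 and tumor_count < config.target_size:
            movers = np.argwhere(can_divide)[rng.random(len(ys)) < p_mig]
            for y, x in movers:
                free = _free_neighbors(state, y, x, _VN, HEALTHY)
                if free and state[y, x] == TUMOR:
                    ty, tx = free[rng.integers(len(free))]
                    state[y, x] = HEALTHY
                    state[ty, tx] = TUMOR
        if use_necrosis and tumor_count < config.target_size:
            m_full = np.empty((n, n))
            m_full[:, 0] = m_full[:, -1] = config.nutrient_boundary
            m_full[:, 1:-1] = m_interior
            tys, txs = np.nonzero(state == TUMOR)
            m_local = np.maximum(m_full[tys, txs], 1e-12)
            p_nec = 1.0 - np.exp(-((config.theta_nec / m_local) ** 2))
            dead = rng.random(len(tys)) < p_nec
            state[tys[dead], txs[dead]] = HEALTHY
            tumor_count -= int(dead.sum())
            if tumor_count == 0:
                raise GrowthStallError(step, 0, "tumor died out (necrosis)")

        if tumor_count >= config.target_size:
            return CAGrid(state, meta={"steps": step, "config": config.to_dict()})

    raise GrowthStallError(config.max_growth_steps, tumor_count, "max growth steps exceeded")


def place_immune_cells(
    grid: CAGrid, gamma: float, config: CAConfig | None = None, pad: float = 3.0
) -> CAGrid:
    """Phase-2 initial condition: effectors over an angular sector.

    The tumor is inscribed in its circumscribing circle (centered on the
    tumor centroid, radius padded by ``pad`` cell diameters so that even a
    perfectly round tumor receives a wrapping shell); every non-tumor site
    inside the circle whose polar angle from the centroid lies in
    [0, gamma) becomes an immune cell.  gamma = 2*pi covers the whole
    remaining disk.
    """
    if not 0 < gamma <= 2 * math.pi + 1e-12:
        raise ValueError(f"gamma must be in (0, 2*pi], got {gamma}")
    tumor = grid.tumor_mask()
    if not tumor.any():
        raise ValueError("no tumor present on the grid")
    ys, xs = np.nonzero(tumor)
    cy, cx = ys.mean(), xs.mean()
    radius = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).max() + pad

    yy, xx = np.mgrid[: grid.n, : grid.n]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    sel = (dist2 <= radius**2) & (grid.state == HEALTHY)
    if gamma < 2 * math.pi:
        ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * math.pi)
        sel &= ang < gamma
    out = grid.copy()
    out.state[sel] = IMMUNE
    out.lysis_count[sel] = 0
    out.meta.update({"gamma": gamma, "centroid": (float(cy), float(cx)), "radius": float(radius)})
    return out


def run_lysis(
    grid: CAGrid,
    config: CAConfig,
    rng: np.random.Generator | None = None,
    step_cap: int | None = None,
) -> LysisSeries:
    """Phase 2: frozen-tumor lysis, one sweep per hour.

    Per step: every immune cell with a tumor cell in its von Neumann
    neighborhood attempts lysis with probability 1 - exp(-1/theta_lys^2);
    attempts are resolved in random order, each claiming a uniformly chosen
    still-present tumor neighbor.  A successful effector moves onto the
    lysed site carrying its kill counter and is removed after ``max_lyses``
    kills; with probability 1 - exp(-1/theta_rec^2) it recruits one new
    immune cell into a free site of its (Moore) neighborhood.  Immune cells
    touching the tumor only diagonally migrate one step onto a free site at
    the lysis front (effectors advance with the shrinking tumor); immune
    cells with no tumor cell in their Moore neighborhood inactivate
    (disappear) with probability 1 - exp(-1/theta_inc^2).  The tumor is
    frozen: its count never increases.

    Returns one record per hour starting at t = 0; ``truncated`` is set if
    the step cap (``step_cap_factor * T0`` by default) is reached or all
    immune cells vanish while tumor remains.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = grid.state.copy()
    counts = grid.lysis_count.copy()
    n = state.shape[0]
    p_lys = _constant_drive_prob(config.theta_lys)
    p_rec = _constant_drive_prob(config.theta_rec)
    p_inc = _constant_drive_prob(config.theta_inc)
    rec_offsets = _MOORE if config.recruit_neighborhood == "moore" else _VN
    max_lyses = config.max_lyses

    t0 = int(np.sum(state == TUMOR))
    if step_cap is None:
        step_cap = config.step_cap_factor * max(t0, 1)
    tumor_series = [t0]
    immune_series = [int(np.sum(state == IMMUNE))]
    truncated = False
    tumor_count = t0

    for _step in range(1, step_cap + 1):
        if tumor_count == 0:
            break
        immune = state == IMMUNE
        if not immune.any():
            truncated = True
            break
        tumor = state == TUMOR
        front = immune & _neighbor_any(tumor, _VN)
        far = immune & ~_neighbor_any(tumor, _MOORE)

        fy, fx = np.nonzero(front)
        attempts = np.flatnonzero(rng.random(len(fy)) < p_lys)
        recruiters = []
        for i in rng.permutation(attempts):
            y, x = int(fy[i]), int(fx[i])
            targets = _free_neighbors(state, y, x, _VN, TUMOR)
            if not targets:
                continue  # target already claimed earlier in the sweep
            ty, tx = targets[rng.integers(len(targets))]
            kills = counts[y, x] + 1
            state[y, x] = HEALTHY
            counts[y, x] = 0
            if kills >= max_lyses:
                state[ty, tx] = HEALTHY  # spent effector removed with its kill
                counts[ty, tx] = 0
            else:
                state[ty, tx] = IMMUNE
                counts[ty, tx] = kills
            tumor_count -= 1
            if rng.random() < p_rec:
                recruiters.append((ty, tx))
            if tumor_count == 0:
                break

        for y, x in recruiters:
            free = _free_neighbors(state, y, x, rec_offsets, HEALTHY)
            if free:
                ry, rx = free[rng.integers(len(free))]
                state[ry, rx] = IMMUNE
                counts[ry, rx] = 0

        # migration: immune cells touching the tumor only diagonally advance
        # onto a free von Neumann site at the lysis front, so effectors keep
        # closing in on the shrinking tumor instead of idling forever
        tumor_now = state == TUMOR
        touches_front = _neighbor_any(tumor_now, _VN)
        middle = (
            (state == IMMUNE)
            & _neighbor_any(tumor_now, _MOORE)
            & ~touches_front
        )
        my, mx = np.nonzero(middle)
        for i in rng.permutation(len(my)):
            y, x = int(my[i]), int(mx[i])
            steps_to_front = [
                (yy, xx)
                for yy, xx in _free_neighbors(state, y, x, _VN, HEALTHY)
                if touches_front[yy, xx]
            ]
            if steps_to_front:
                ty, tx = steps_to_front[rng.integers(len(steps_to_front))]
                state[ty, tx] = IMMUNE
                counts[ty, tx] = counts[y, x]
                state[y, x] = HEALTHY
                counts[y, x] = 0

        if p_inc > 0:
            iy, ix = np.nonzero(far)
            gone = rng.random(len(iy)) < p_inc
            state[iy[gone], ix[gone]] = HEALTHY

        tumor_series.append(tumor_count)
        immune_series.append(int(np.sum(state == IMMUNE)))
    else:
        truncated = tumor_count > 0

    series = LysisSeries(
        time_hr=np.arange(len(tumor_series), dtype=float),
        tumor_cells=np.array(tumor_series, dtype=float),
        immune_cells=np.array(immune_series, dtype=float),
        truncated=truncated,
    )
    series.meta.update({"config": config.to_dict(), "final_grid_counts": {
        "tumor": tumor_count, "immune": immune_series[-1]}})
    return series


def run_experiment(
    preset: str,
    gamma: float,
    seed: int = 0,
    n: int = 300,
    target_size: int = 9100,
    grown: CAGrid | None = None,
    **overrides,
) -> LysisSeries:
    """Grow (or reuse) a preset tumor, cover an angle gamma, run the lysis.

    All randomness derives from ``seed`` (growth and lysis streams are
    spawned from it); passing the same arguments reproduces the series
    exactly.  A pre-grown grid can be supplied to reuse one tumor across
    several lysis initial conditions, as in the reference protocol.
    """
    config = preset_config(preset, n=n, target_size=target_size, seed=seed, **overrides)
    ss = np.random.SeedSequence(seed)
    grow_rng, lysis_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    if grown is None:
        grown = grow_tumor(config, rng=grow_rng)
    covered = place_immune_cells(grown, gamma, config)
    series = run_lysis(covered, config, rng=lysis_rng)
    series.meta.update({"preset": preset, "gamma": gamma, "seed": seed})
    return series


def erode_ball_3d(R0: float, steps: int | None = None) -> np.ndarray:
    """Volumes of a 3-D ball eroded at unit radial speed, one layer per step.

    V_n = (4/3) pi (R0 - n)^3 clamped at zero — the three-dimensional
    analogue of the disk map; a power-law fit of this sequence recovers an
    exponent near 2/3 (surface-to-volume scaling of a solid tumor).
    """
    if R0 <= 0:
        raise ValueError("R0 must be > 0")
    if steps is None:
        steps = int(math.ceil(R0))
    if steps < 0:
        raise ValueError("steps must be >= 0")
    radii = np.maximum(R0 - np.arange(steps + 1, dtype=float), 0.0)
    return (4.0 / 3.0) * math.pi * radii**3


def morphology_metrics(mask: np.ndarray) -> dict:
    """Area, perimeter and isoperimetric ratio 4*pi*A/P^2 of a tumor mask.

    The ratio is 1 for a perfect disk and decreases with branchiness, so it
    orders the presets spherical > papillary > filamentary.
    """
    from skimage.measure import perimeter as _perimeter

    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    per = float(_perimeter(mask, neighborhood=4))
    iso = 4.0 * math.pi * area / per**2 if per > 0 else math.inf
    return {"area": area, "perimeter": per, "isoperimetric_ratio": iso}
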