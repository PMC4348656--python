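"""Implicit-solvent relaxation of coarse-grained vesicles.

The bead force field is a deliberately simple stand-in for a full
explicit-solvent CG MD treatment, built from four terms:

* harmonic bonds along each lipid's bead chain (rest lengths from the
  template geometry),
* harmonic angles on head-stack and tail triples (chain stiffness),
* truncated-and-shifted 12-6 Lennard-Jones interactions between beads of
  different lipids, with hydrophobic–hydrophobic cohesion three times the
  head–head well depth (this asymmetry is what drives tail burial and pore
  closure), and
* an implicit-solvent exposure penalty: each hydrophobic bead pays an
  energy proportional to a smooth estimate of its solvent exposure (a
  decaying function of the local bead density), emulating the hydrophobic
  effect of the missing explicit water.

Relaxation is damped gradient descent with backtracking (the energy trace
is non-increasing across accepted steps).  Thermal motion is emulated only
as post-minimization Gaussian jitter used to generate snapshot ensembles
for surface averaging.

Stabilization diagnostics follow the conventional criteria for a relaxed
vesicle: the surface pore is closed, the head-bead radial distribution
about the center of mass shows a sharp (spherical) shell, and the surface
hydrophobicity has stabilized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dfield

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .vesicle import ANGLE_TRIPLES, CGVesicle, fibonacci_sphere

__all__ = [
    "ForceField",
    "RelaxConfig",
    "RelaxReport",
    "RDFResult",
    "energy_and_forces",
    "minimize",
    "pore_closed",
    "radial_distribution",
]


@dataclass(frozen=True)
class ForceField:
    """Stand-in CG force field (arbitrary energy units ~ thermal scale).

    Parameters
    ----------
    bond_k : float
        Harmonic bond constant (energy/Å²); rest lengths come from the
        lipid template.
    angle_k : float
        Harmonic angle constant (energy/rad²); rest angles from the template.
    epsilon_hh, epsilon_ht, epsilon_tt : float
        LJ well depths by hydrophobicity-class pair (head–head, head–tail,
        tail–tail).  Tail–tail cohesion is the strongest (default 3× hh).
    sigma_hh, sigma_ht, sigma_tt : float
        LJ diameters (Å) by class pair.  Head beads carry an implicit
        hydration shell, so the head–head diameter is close to the
        65 Å²-per-lipid lattice spacing (this pins the lateral density of
        the head lattice near the built value); tail beads use the bare CG
        bead diameter 4.7 Å.
    cutoff : float
        LJ cutoff (Å); the potential is shifted to zero there.
    solvation_strength : float
        Energy per Å² of exposure proxy charged to hydrophobic beads.
    solvation_cutoff : float
        Range (Å) of the local-density kernel used by the exposure proxy.
    solvation_rho0 : float
        Density scale: exposure = exp(−rho/rho0), so beads with local
        density well above rho0 are treated as buried.
    """

    bond_k: float = 10.0
    angle_k: float = 5.0
    epsilon_hh: float = 0.5
    epsilon_ht: float = 0.5
    epsilon_tt: float = 1.5
    sigma_hh: float = 9.1
    sigma_ht: float = 6.9
    sigma_tt: float = 4.7
    cutoff: float = 12.0
    solvation_strength: float = 0.03
    solvation_cutoff: float = 7.0
    solvation_rho0: float = 4.0

    def __post_init__(self) -> None:
        for name in ("bond_k", "angle_k", "epsilon_hh", "epsilon_ht", "epsilon_tt",
                     "sigma_hh", "sigma_ht", "sigma_tt", "cutoff",
                     "solvation_cutoff", "solvation_rho0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.solvation_strength < 0:
            raise ValueError("solvation_strength must be >= 0")

    def epsilon_matrix(self) -> np.ndarray:
        """2×2 well-depth lookup indexed by hydrophobicity (0=philic, 1=phobic)."""
        return np.array([[self.epsilon_hh, self.epsilon_ht],
                         [self.epsilon_ht, self.epsilon_tt]])

    def sigma_matrix(self) -> np.ndarray:
        """2×2 LJ-diameter lookup indexed like :meth:`epsilon_matrix`."""
        return np.array([[self.sigma_hh, self.sigma_ht],
                         [self.sigma_ht, self.sigma_tt]])


@dataclass(frozen=True)
class RelaxConfig:
    """Minimization schedule, pore-healing moves and snapshot-jitter settings.

    Gradient descent alone cannot reproduce the lateral lipid diffusion that
    lets a thermal simulation close a wide pore — the lattice jams.  Pore
    healing therefore applies collective tangential moves: an
    area-preserving angular remap that advects every lipid a few degrees
    toward the pore, followed by descent; each move block is accepted only
    if it ends at a lower energy than before the move, so the recorded
    energy trace of accepted states remains non-increasing and the force
    field (not the move) decides whether closure is favorable.
    """

    max_steps: int = 2500
    force_tolerance: float = 0.05  # inf-norm of per-bead force
    initial_step: float = 0.05  # Å per unit force
    max_displacement: float = 0.5  # Å per step, per bead
    heal_pore: bool = True
    heal_delta_deg: float = 3.0  # angular advection per healing move
    heal_max_moves: int = 60
    heal_recover_steps: int = 150  # descent budget to re-equilibrate a move
    heal_stop_angle_deg: float = 8.0  # hole size below which healing stops
    jitter_amplitude: float = 1.7  # Å, thermal-roughness scale per coordinate
    n_snapshots: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.force_tolerance <= 0:
            raise ValueError("force_tolerance must be positive")
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.heal_delta_deg <= 0:
            raise ValueError("heal_delta_deg must be positive")


@dataclass
class RDFResult:
    """Head-bead radial profile about the center of mass."""

    bin_centers: np.ndarray  # Å
    counts: np.ndarray
    peak_radius: float  # Å, outer head shell
    fwhm: float  # Å
    sphericity: float  # fwhm / peak_radius (smaller = more spherical)
    equilibrated_diameter_nm: float  # 2 * mean outer-head radius


@dataclass
class RelaxReport:
    """Outcome of a relaxation run."""

    energy_trace: np.ndarray
    n_steps: int
    converged: bool
    force_inf_norm: float
    final_diameter_nm: float
    pore_closed: bool
    rdf_sphericity: float
    snapshots: list = _dfield(default_factory=list)
    termination: str = ""


def _scatter_add(F: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """F[idx] += vals via bincount (much faster than np.add.at)."""
    n = len(F)
    for c in range(3):
        F[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


class _Topology:
    """Precomputed per-vesicle bonded terms and class indices."""

    def __init__(self, v: CGVesicle):
        t = v.template
        n_lip = v.n_lipids
        bonds = np.asarray(t.bonds, dtype=int)
        offsets = (np.arange(n_lip) * 13)[:, None, None]
        self.bond_idx = (bonds[None, :, :] + offsets).reshape(-1, 2)
        self.bond_r0 = np.tile(t.bond_rest_lengths(), n_lip)
        triples = np.asarray(ANGLE_TRIPLES, dtype=int)
        self.angle_idx = (triples[None, :, :] + offsets).reshape(-1, 3)
        lc = t.local_coords
        th0 = []
        for a, b, c in ANGLE_TRIPLES:
            u = lc[a] - lc[b]
            w = lc[c] - lc[b]
            cosab = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
            th0.append(np.arccos(np.clip(cosab, -1.0, 1.0)))
        self.angle_theta0 = np.tile(np.array(th0), n_lip)
        self.hclass = v.hydrophobic_mask.astype(int)  # 0 philic, 1 phobic
        self.lipid_index = v.lipid_index


def _bond_energy_forces(x, topo: _Topology, ff: ForceField, F):
    i, j = topo.bond_idx[:, 0], topo.bond_idx[:, 1]
    d = x[i] - x[j]
    r = np.linalg.norm(d, axis=1)
    dr = r - topo.bond_r0
    E = float(ff.bond_k * np.sum(dr**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(r > 1e-12, 2.0 * ff.bond_k * dr / r, 0.0)[:, None] * d
    _scatter_add(F, i, -g)
    _scatter_add(F, j, g)
    return E


def _angle_energy_forces(x, topo: _Topology, ff: ForceField, F):
    ia, ib, ic = topo.angle_idx.T
    u = x[ia] - x[ib]
    w = x[ic] - x[ib]
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    uh = u / nu[:, None]
    wh = w / nw[:, None]
    cos_t = np.clip(np.sum(uh * wh, axis=1), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dth = theta - topo.angle_theta0
    E = float(ff.angle_k * np.sum(dth**2))
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
    coef = 2.0 * ff.angle_k * dth
    # dtheta/da and dtheta/dc (standard angle gradient)
    ga = (cos_t[:, None] * uh - wh) / (nu * sin_t)[:, None]
    gc = (cos_t[:, None] * wh - uh) / (nw * sin_t)[:, None]
    _scatter_add(F, ia, -coef[:, None] * ga)
    _scatter_add(F, ic, -coef[:, None] * gc)
    _scatter_add(F, ib, coef[:, None] * (ga + gc))
    return E


@njit(cache=True, fastmath=True)
def _pair_kernel(x, pairs, lipid_index, hclass, eps_mat, sig_mat, cutoff,
                 c_solv, rc_solv, rho0, F):
    """LJ (inter-lipid, truncated/shifted, linear-capped core) plus the
    implicit-solvent exposure penalty, accumulated into F.  Returns
    (energy, n_coincident)."""
    m = pairs.shape[0]
    n = x.shape[0]
    E = 0.0
    n_coincident = 0
    rho = np.zeros(n)
    # pass 1: LJ forces + solvation density
    for p in range(m):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < cutoff and lipid_index[i] != lipid_index[j]:
            eps = eps_mat[hclass[i], hclass[j]]
            sig = sig_mat[hclass[i], hclass[j]]
            r_cap = 0.8 * sig
            if r < 1e-9:
                n_coincident += 1
            rs = r if r > r_cap else r_cap
            sr6 = (sig / rs) ** 6
            sr6c = (sig / cutoff) ** 6
            v_shift = 4.0 * eps * (sr6c * sr6c - sr6c)
            V = 4.0 * eps * (sr6 * sr6 - sr6) - v_shift
            dVdr = 24.0 * eps * (sr6 - 2.0 * sr6 * sr6) / rs
            if r < r_cap:
                V += dVdr * (r - r_cap)
            E += V
            if r > 1e-12:
                g = dVdr / r
                F[i, 0] -= g * dx
                F[i, 1] -= g * dy
                F[i, 2] -= g * dz
                F[j, 0] += g * dx
                F[j, 1] += g * dy
                F[j, 2] += g * dz
        if c_solv > 0.0 and r < rc_solv:
            q2 = r2 / (rc_solv * rc_solv)
            w = (1.0 - q2) * (1.0 - q2)
            rho[i] += w
            rho[j] += w
    if c_solv > 0.0:
        sprime = np.zeros(n)
        for i in range(n):
            if hclass[i] == 1:
                s = np.exp(-rho[i] / rho0)
                E += c_solv * s
                sprime[i] = -s / rho0
        # pass 2: solvation forces
        for p in range(m):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc_solv * rc_solv:
                r = np.sqrt(r2)
                if r > 1e-12:
                    q2 = r2 / (rc_solv * rc_solv)
                    wprime = -4.0 * r / (rc_solv * rc_solv) * (1.0 - q2)
                    coef = c_solv * (sprime[i] + sprime[j]) * wprime / r
                    F[i, 0] -= coef * dx
                    F[i, 1] -= coef * dy
                    F[i, 2] -= coef * dz
                    F[j, 0] += coef * dx
                    F[j, 1] += coef * dy
                    F[j, 2] += coef * dz
    return E, n_coincident


#: Reference fully-exposed bead area (Å²) scaling the solvation penalty.
_A0_EXPOSED = 4.0 * np.pi * (2.35 + 1.4) ** 2


def _pair_energy_forces(x, pairs, topo: _Topology, ff: ForceField, F):
    """LJ (inter-lipid) + implicit-solvent exposure penalty on one pair list."""
    E, n_coincident = _pair_kernel(
        x, pairs, topo.lipid_index, topo.hclass,
        ff.epsilon_matrix(), ff.sigma_matrix(), ff.cutoff,
        ff.solvation_strength * _A0_EXPOSED, ff.solvation_cutoff,
        ff.solvation_rho0, F,
    )
    if n_coincident:
        warnings.warn("coincident beads encountered; repulsion capped")
    return float(E)


def _build_pairs(x: np.ndarray, r_list: float) -> np.ndarray:
    pairs = cKDTree(x).query_pairs(r=r_list, output_type="ndarray")
    return pairs if len(pairs) else np.empty((0, 2), dtype=int)


def energy_and_forces(
    v: CGVesicle,
    ff: ForceField,
    coords: np.ndarray | None = None,
    pairs: np.ndarray | None = None,
    topo: _Topology | None = None,
) -> tuple[float, np.ndarray]:
    """Total energy and per-bead forces (negative energy gradient).

    ``coords``/``pairs``/``topo`` allow the minimizer to reuse its neighbor
    list and topology; the public one-argument form recomputes everything.
    """
    x = v.coords if coords is None else coords
    topo = topo or _Topology(v)
    if pairs is None:
        pairs = _build_pairs(x, max(ff.cutoff, ff.solvation_cutoff))
    F = np.zeros_like(x)
    E = _bond_energy_forces(x, topo, ff, F)
    E += _angle_energy_forces(x, topo, ff, F)
    if len(pairs):
        E += _pair_energy_forces(x, pairs, topo, ff, F)
    return E, F


def largest_empty_cap(v: CGVesicle, coords: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Direction and half-angle (degrees) of the largest head-free spherical
    cap on the outer head shell — the pore locator."""
    x = v.coords if coords is None else coords
    com = x.mean(axis=0)
    m = v.head_mask & (v.leaflet_of_beads() == "outer")
    heads = x[m] - com
    heads /= np.linalg.norm(heads, axis=1, keepdims=True)
    mesh = fibonacci_sphere(20000)
    best = np.empty(len(mesh))
    for start in range(0, len(mesh), 4096):
        best[start:start + 4096] = (mesh[start:start + 4096] @ heads.T).max(axis=1)
    k = int(np.argmin(best))
    return mesh[k], float(np.degrees(np.arccos(np.clip(best[k], -1.0, 1.0))))


def _advect_toward_axis(x: np.ndarray, lipid_index: np.ndarray, axis: np.ndarray,
                        alpha_deg: float, delta_deg: float) -> np.ndarray:
    """Area-preserving angular remap pulling every lipid toward ``axis``.

    Lipids occupy polar angles (from the pore axis) in roughly
    [alpha, 180°]; the map sends cos(theta) linearly onto the range
    corresponding to [alpha − delta, 180°], shrinking the empty cap by
    ``delta_deg`` while stretching the covered region uniformly in solid
    angle.  Each lipid rotates rigidly about the center of mass.
    """
    com = x.mean(axis=0)
    n_lip = int(lipid_index.max()) + 1
    centroids = np.zeros((n_lip, 3))
    _scatter_add(centroids, lipid_index, x - com)
    u = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    c = u @ axis
    cos_a = np.cos(np.radians(alpha_deg))
    cos_ap = np.cos(np.radians(max(alpha_deg - delta_deg, 0.0)))
    # linear map of cos(theta): [-1, cos_a] -> [-1, cos_ap]
    scale = (1.0 + cos_ap) / (1.0 + cos_a)
    c_new = np.clip(-1.0 + (np.clip(c, -1.0, cos_a) + 1.0) * scale, -1.0, 1.0)
    dtheta = np.arccos(np.clip(c, -1.0, 1.0)) - np.arccos(c_new)  # > 0: toward axis

    # rotation axis chosen so +dtheta carries u toward the pore axis
    k = np.cross(u, np.broadcast_to(axis, u.shape))
    k_norm = np.linalg.norm(k, axis=1, keepdims=True)
    ok = (k_norm[:, 0] > 1e-9) & (np.abs(dtheta) > 1e-12)
    k = np.where(k_norm > 1e-12, k / np.maximum(k_norm, 1e-12), 0.0)
    # Rodrigues rotation of each lipid's beads about k by +dtheta
    out = x.copy()
    p = x - com
    kb = k[lipid_index]
    th = np.where(ok, dtheta, 0.0)[lipid_index][:, None]
    cos_t, sin_t = np.cos(th), np.sin(th)
    out = com + p * cos_t + np.cross(kb, p) * sin_t + kb * (np.sum(kb * p, axis=1, keepdims=True)) * (1.0 - cos_t)
    return out


class _Descent:
    """Backtracking gradient descent with a reusable neighbor list."""

    def __init__(self, v: CGVesicle, ff: ForceField, cfg: RelaxConfig, x: np.ndarray):
        self.v, self.ff, self.cfg = v, ff, cfg
        self.topo = _Topology(v)
        self.skin = 2.0
        self.r_list = max(ff.cutoff, ff.solvation_cutoff) + self.skin
        self.x = x.copy()
        self.pairs = _build_pairs(self.x, self.r_list)
        self.x_ref = self.x.copy()
        self.alpha = cfg.initial_step
        self.E, self.F = energy_and_forces(v, ff, coords=self.x, pairs=self.pairs, topo=self.topo)
        if not np.isfinite(self.E):
            raise RuntimeError("initial configuration has non-finite energy")
        self.fmax = float(np.abs(self.F).max())

    def set_coords(self, x: np.ndarray) -> None:
        self.x = x.copy()
        self.pairs = _build_pairs(self.x, self.r_list)
        self.x_ref = self.x.copy()
        self.E, self.F = energy_and_forces(
            self.v, self.ff, coords=self.x, pairs=self.pairs, topo=self.topo
        )
        self.fmax = float(np.abs(self.F).max())
        self.alpha = self.cfg.initial_step

    def run(self, budget: int, stop_energy: float | None = None) -> tuple[int, str]:
        """Descend for up to ``budget`` accepted steps.

        Returns (steps_taken, reason); reason one of force_tolerance,
        budget, line_search_stalled, below_stop_energy.
        """
        cfg = self.cfg
        step = 0
        while step < budget:
            if self.fmax < cfg.force_tolerance:
                return step, "force_tolerance"
            if stop_energy is not None and self.E < stop_energy:
                return step, "below_stop_energy"
            accepted = False
            while self.alpha > 1e-12:
                dx = self.alpha * self.F
                dmax = float(np.linalg.norm(dx, axis=1).max())
                if dmax > cfg.max_displacement:
                    dx *= cfg.max_displacement / dmax
                x_new = self.x + dx
                drift = float(np.linalg.norm(x_new - self.x_ref, axis=1).max())
                if drift > 0.5 * self.skin:
                    self.pairs = _build_pairs(x_new, self.r_list)
                    self.x_ref = x_new.copy()
                E_new, F_new = energy_and_forces(
                    self.v, self.ff, coords=x_new, pairs=self.pairs, topo=self.topo
                )
                if not np.isfinite(E_new):
                    raise RuntimeError("divergence: non-finite energy during descent")
                if E_new <= self.E + 1e-10 * max(1.0, abs(self.E)):
                    self.x, self.E, self.F = x_new, E_new, F_new
                    self.fmax = float(np.abs(F_new).max())
                    self.alpha = min(self.alpha * 1.2, 1.0)
                    accepted = True
                    break
                self.alpha *= 0.5
            if not accepted:
                self.alpha = self.cfg.initial_step
                return step, "line_search_stalled"
            step += 1
        return step, "budget"


def minimize(
    v: CGVesicle,
    ff: ForceField | None = None,
    cfg: RelaxConfig | None = None,
) -> tuple[CGVesicle, RelaxReport]:
    """Relax a vesicle: damped gradient descent plus optional pore healing.

    Descent steps move each bead along the net force (largest single-bead
    displacement capped at ``cfg.max_displacement``) and are accepted only
    if the energy does not increase.  If a pore remains open once plain
    descent stalls, collective healing moves (see :class:`RelaxConfig`)
    advect lipids toward the hole; each move block is kept only when it
    ends below the pre-move energy, so the recorded trace of accepted
    states is non-increasing.  Terminates on the force tolerance, the
    total step budget, or a stalled line search.  The report carries
    pore/sphericity diagnostics of the final state and ``cfg.n_snapshots``
    thermally jittered copies for surface averaging.
    """
    ff = ff or ForceField()
    cfg = cfg or RelaxConfig()
    des = _Descent(v, ff, cfg, v.coords)
    trace = [des.E]
    budget = cfg.max_steps
    # initial settle: relieve build strain before attempting pore healing
    used, reason = des.run(min(300, budget) if cfg.heal_pore else budget)
    budget -= used
    trace.append(des.E)
    termination = {"budget": "max_steps"}.get(reason, reason)

    if cfg.heal_pore:
        moves_left = cfg.heal_max_moves
        # healing rounds: advect/descend until the hole stays closed through
        # a full descent phase (closure can partially relax back open)
        for _round in range(4):
            rejected = False
            while moves_left > 0 and budget > 0:
                axis, hole_deg = largest_empty_cap(v, des.x)
                if hole_deg <= cfg.heal_stop_angle_deg:
                    break
                E_before = des.E
                x_before = des.x.copy()
                x_moved = _advect_toward_axis(des.x, v.lipid_index, axis,
                                              hole_deg, cfg.heal_delta_deg)
                des.set_coords(x_moved)
                used, _ = des.run(min(cfg.heal_recover_steps, budget),
                                  stop_energy=E_before)
                budget -= used
                moves_left -= 1
                if des.E <= E_before:
                    trace.append(des.E)  # accepted healing block
                else:
                    des.set_coords(x_before)  # revert: closure not favorable
                    termination = "healing_rejected"
                    rejected = True
                    break
            # bounded polish so later rounds keep a healing budget
            polish = min(budget, 4 * cfg.heal_recover_steps)
            if polish > 0 and des.fmax >= cfg.force_tolerance:
                used, reason = des.run(polish)
                budget -= used
                trace.append(des.E)
            _, hole_deg = largest_empty_cap(v, des.x)
            if rejected or hole_deg <= cfg.heal_stop_angle_deg or moves_left <= 0 or budget <= 0:
                break
        if budget > 0 and des.fmax >= cfg.force_tolerance:
            used, reason = des.run(budget)
            budget -= used
            trace.append(des.E)
            termination = {"budget": "max_steps"}.get(reason, reason)

    x = des.x
    fmax = des.fmax
    step = cfg.max_steps - budget
    relaxed = v.copy_with_coords(x)
    rdf = radial_distribution(relaxed)
    closed = pore_closed(relaxed)
    rng = np.random.default_rng(cfg.seed)
    snaps = [
        relaxed.copy_with_coords(x + rng.normal(0.0, cfg.jitter_amplitude, size=x.shape))
        for _ in range(cfg.n_snapshots)
    ]
    report = RelaxReport(
        energy_trace=np.array(trace),
        n_steps=step,
        converged=termination == "force_tolerance",
        force_inf_norm=fmax,
        final_diameter_nm=rdf.equilibrated_diameter_nm,
        pore_closed=closed,
        rdf_sphericity=rdf.sphericity,
        snapshots=snaps,
        termination=termination,
    )
    return relaxed, report


def pore_closed(v: CGVesicle, max_hole_fraction: float = 0.02, mesh_deg: float = 1.0) -> bool:
    """True iff no spherical cap of area fraction > ``max_hole_fraction`` on
    the outer head shell is empty of head beads.

    Cap centers are searched on an approximately ``mesh_deg``-degree mesh of
    directions (Fibonacci lattice); a hole exists where the nearest
    outer-leaflet choline direction is farther than the cap half-angle."""
    com = v.coords.mean(axis=0)
    m = v.head_mask & (v.leaflet_of_beads() == "outer")
    heads = v.coords[m] - com
    heads /= np.linalg.norm(heads, axis=1, keepdims=True)
    theta_cap = np.arccos(1.0 - 2.0 * max_hole_fraction)
    n_mesh = max(1000, int(round(4.0 * 180.0**2 / np.pi / mesh_deg**2)))
    mesh = fibonacci_sphere(n_mesh)
    cos_cap = np.cos(theta_cap)
    # chunked max-dot: a direction is covered if some head lies within theta_cap
    for start in range(0, n_mesh, 4096):
        block = mesh[start:start + 4096]
        best = (block @ heads.T).max(axis=1)
        if np.any(best < cos_cap):
            return False
    return True


def radial_distribution(v: CGVesicle, bin_width: float = 1.0) -> RDFResult:
    """Head-bead radial histogram about the center of mass, with the
    sphericity diagnostic (outer-peak FWHM over peak radius) and the
    equilibrated diameter (2 × mean outer-leaflet head radius, nm)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    com = v.coords.mean(axis=0)
    heads = v.head_mask
    r_all = np.linalg.norm(v.coords[heads] - com, axis=1)
    edges = np.arange(0.0, r_all.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(r_all, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    r_out = v.outer_head_radii()
    h_out, _ = np.histogram(r_out, bins=edges)
    k = int(np.argmax(h_out))
    peak_r = float(centers[k])
    half = h_out[k] / 2.0
    # walk out from the peak to the half-maximum crossings (linear interp)
    lo = hi = float(centers[k])
    for t in range(k, -1, -1):
        if h_out[t] < half:
            frac = (half - h_out[t]) / max(h_out[t + 1] - h_out[t], 1e-12)
            lo = centers[t] + frac * bin_width
            break
    for t in range(k, len(h_out)):
        if h_out[t] < half:
            frac = (half - h_out[t]) / max(h_out[t - 1] - h_out[t], 1e-12)
            hi = centers[t] - frac * bin_width
            break
    fwhm = max(hi - lo, 0.0)
    if fwhm == 0.0:  # delta-like shell narrower than one bin
        fwhm = min(2.355 * float(np.std(r_out)), bin_width)
    return RDFResult(
        bin_centers=centers,
        counts=counts,
        peak_radius=peak_r,
        fwhm=float(fwhm),
        sphericity=float(fwhm / peak_r),
        equilibrated_diameter_nm=float(2.0 * r_out.mean() / 10.0),
    )
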