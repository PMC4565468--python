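"""Electric-field computation with field-dependent conductivity.

Solves the static conduction equation ``∇·(σ∇u) = 0`` on the voxel grid with
a flux-conservative 7-point finite-volume discretization (harmonic-mean face
conductivities), Dirichlet conditions on the active electrode pair and
homogeneous Neumann walls. Electroporation raises tissue conductivity: after
each linear solve the conductivity is updated voxelwise to
``max(σ_old, σ(E))`` and the solve repeats until the increase stalls. Pulses
are applied across successive electrode pairs; the delivered dose is the
voxelwise maximum field over all pairs.

Units: spacings mm, conductivities S/m, potentials V, fields V/cm.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

__all__ = [
    "TissueProperties",
    "PulseProtocol",
    "FieldSolution",
    "load_tissue_config",
    "default_protocols",
    "protocol_thresholds",
    "properties_by_label",
    "sigma_of_E",
    "solve_pair",
    "field_magnitude",
    "electrode_current",
    "solve_nonlinear_pair",
    "solve_sequence",
]

MM_TO_CM = 0.1  # V/mm -> V/cm multiplier is 10; gradient in 1/mm * 10


@dataclass(frozen=True)
class TissueProperties:
    """Electrical behaviour of one tissue."""

    name: str
    sigma0: float  # baseline conductivity, S/m
    sigma_max: float  # post-electroporation conductivity, S/m
    e_low: float  # sigmoid transition start, V/cm
    e_high: float  # sigmoid transition end, V/cm
    e_rev: float = 400.0  # reversible threshold, V/cm
    e_irr: float = 800.0  # irreversible threshold, V/cm

    def __post_init__(self):
        if not (self.sigma_max >= self.sigma0 > 0):
            raise ValueError(f"{self.name}: need sigma_max >= sigma0 > 0")
        if not (0 < self.e_low <= self.e_high):
            raise ValueError(f"{self.name}: need 0 < e_low <= e_high")
        if not (0 < self.e_rev <= self.e_irr):
            raise ValueError(f"{self.name}: need 0 < e_rev <= e_irr")


@dataclass(frozen=True)
class PulseProtocol:
    mode: str  # ECT | IRE
    pulse_count: int
    pulse_duration_us: float
    frequency_hz: float

    def __post_init__(self):
        if min(self.pulse_count, self.pulse_duration_us, self.frequency_hz) <= 0:
            raise ValueError("protocol fields must be positive")

    def key(self):
        return (self.mode, self.pulse_count, self.pulse_duration_us,
                self.frequency_hz)


@dataclass
class FieldSolution:
    """Result of a full pair-sequence solve."""

    potentials: List[np.ndarray]
    voltages: List[float]
    pair_fields: List[np.ndarray]  # V/cm per pair
    cumulative_field: np.ndarray  # voxelwise max over pairs, V/cm
    conductivity: np.ndarray  # final sigma state, S/m
    iterations: List[int]
    converged: List[bool]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)


def _load_config(path=None) -> dict:
    if path is None:
        ref = importlib.resources.files("eptplan") / "data" / "tissues.yaml"
        return yaml.safe_load(ref.read_text())
    with open(path) as f:
        return yaml.safe_load(f)


def default_protocols(path=None) -> Dict[str, PulseProtocol]:
    """The two calibrated pulse protocols shipped with the package."""
    cfg = _load_config(path)
    out = {}
    for p in cfg["protocols"]:
        out[p["mode"]] = PulseProtocol(p["mode"], int(p["pulse_count"]),
                                       float(p["pulse_duration_us"]),
                                       float(p["frequency_hz"]))
    return out


def protocol_thresholds(protocol: PulseProtocol, path=None) -> Dict[str, Tuple[float, float]]:
    """Per-tissue (reversible, irreversible) thresholds for a protocol.

    Only protocols present in the shipped (or provided) configuration are
    calibrated; anything else raises, directing the user to supply custom
    thresholds rather than silently falling back.
    """
    cfg = _load_config(path)
    for p in cfg["protocols"]:
        cand = PulseProtocol(p["mode"], int(p["pulse_count"]),
                             float(p["pulse_duration_us"]), float(p["frequency_hz"]))
        if cand.key() == protocol.key():
            thr = {t: tuple(map(float, v)) for t, v in p["thresholds"].items()}
            default = thr.get("default")
            for tissue in cfg["tissues"]:
                thr.setdefault(tissue, default)
            return thr
    raise KeyError(
        f"no calibrated thresholds for protocol {protocol.key()}; "
        "supply a custom tissue-threshold configuration"
    )


def load_tissue_config(protocol: Optional[PulseProtocol] = None,
                       path=None) -> Dict[str, TissueProperties]:
    """Tissue property table, thresholds resolved for ``protocol`` if given."""
    cfg = _load_config(path)
    thr = protocol_thresholds(protocol, path) if protocol is not None else {}
    table = {}
    for name, p in cfg["tissues"].items():
        e_rev, e_irr = thr.get(name, (400.0, 800.0))
        table[name] = TissueProperties(
            name, float(p["sigma0"]), float(p["sigma_max"]),
            float(p["e_low"]), float(p["e_high"]), e_rev, e_irr,
        )
    return table


def properties_by_label(mask_table: Dict[int, str],
                        tissue_table: Dict[str, TissueProperties],
                        background: str = "background") -> Dict[int, TissueProperties]:
    """Map integer mask labels (plus 0) to tissue properties."""
    out = {0: tissue_table[background]}
    for lab, name in mask_table.items():
        if name not in tissue_table:
            raise KeyError(f"tissue {name!r} missing from property table")
        out[int(lab)] = tissue_table[name]
    return out


# ---------------------------------------------------------------------------
# sigma(E)


def sigma_of_E(E: np.ndarray, labels: np.ndarray,
               props: Dict[int, TissueProperties]) -> np.ndarray:
    """Field-dependent conductivity, voxel by voxel.

    Below ``e_low`` the tissue keeps its baseline σ0; above ``e_high`` it is
    fully permeabilized at σmax; in between a symmetric cubic smoothstep
    interpolates (so the transition midpoint maps exactly to (σ0+σmax)/2).
    """
    present = np.unique(labels)
    missing = set(present.tolist()) - set(props)
    if missing:
        raise KeyError(f"labels {sorted(missing)} have no tissue properties")
    sigma = np.empty(E.shape, dtype=np.float64)
    for lab in present:
        sel = labels == lab
        p = props[int(lab)]
        if p.e_high > p.e_low:
            t = np.clip((E[sel] - p.e_low) / (p.e_high - p.e_low), 0.0, 1.0)
        else:
            t = (E[sel] >= p.e_low).astype(np.float64)
        s = t * t * (3.0 - 2.0 * t)
        sigma[sel] = p.sigma0 + (p.sigma_max - p.sigma0) * s
    return sigma


# ---------------------------------------------------------------------------
# linear solve


def _face_conductances(sigma: np.ndarray, spacing) -> List[np.ndarray]:
    """Harmonic-mean conductance of every interior face, per axis, in S."""
    out = []
    for ax in range(3):
        s1 = np.moveaxis(sigma, ax, 0)[:-1]
        s2 = np.moveaxis(sigma, ax, 0)[1:]
        harm = 2.0 * s1 * s2 / (s1 + s2)
        area = np.prod([spacing[a] for a in range(3) if a != ax])
        g = harm * area / spacing[ax] * 1e-3  # S/m * mm -> S
        out.append(np.moveaxis(g, 0, ax))
    return out


def solve_pair(sigma: np.ndarray, electrode_labels: np.ndarray,
               pair: Tuple[int, int], voltage: float,
               spacing=(1.0, 1.0, 1.0), rtol: float = 1e-8) -> np.ndarray:
    """Solve ``∇·(σ∇u) = 0`` for one active electrode pair.

    ``u = voltage`` on the needle labeled ``pair[0] + 1``, ``u = 0`` on
    ``pair[1] + 1``; inactive needles are omitted (their voxels behave as
    tissue); homogeneous Neumann on the outer boundary. Returns the potential
    grid, solved to a relative residual ≤ ``rtol``.
    """
    if np.any(sigma <= 0):
        raise ValueError("conductivity must be strictly positive")
    shape = sigma.shape
    n = int(np.prod(shape))
    anode = electrode_labels == pair[0] + 1
    cathode = electrode_labels == pair[1] + 1
    if not anode.any() or not cathode.any():
        raise ValueError(f"electrode pair {pair} has no rasterized voxels")

    idx = np.arange(n).reshape(shape)
    g = _face_conductances(sigma, spacing)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ax in range(3):
        # ravel in the moved layout so conductances align with the index pairs
        gi = np.moveaxis(g[ax], ax, 0).ravel()
        left = np.moveaxis(idx, ax, 0)[:-1].ravel()
        right = np.moveaxis(idx, ax, 0)[1:].ravel()
        rows.append(left)
        cols.append(right)
        vals.append(-gi)
        rows.append(right)
        cols.append(left)
        vals.append(-gi)
        np.add.at(diag, left, gi)
        np.add.at(diag, right, gi)

    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    fixed = anode.ravel() | cathode.ravel()
    b = np.zeros(n)
    u_fixed = np.where(anode.ravel(), float(voltage), 0.0)
    # move Dirichlet columns to the RHS, then overwrite their rows by identity
    b -= A @ (u_fixed * fixed)
    b[fixed] = u_fixed[fixed]
    mask_free = ~fixed
    D = sparse.diags(mask_free.astype(float))
    A = D @ A @ D + sparse.diags(fixed.astype(float))
    A = A.tocsr()
    b = b * mask_free + u_fixed * fixed

    # the Dirichlet-symmetrized operator is SPD: Jacobi-preconditioned CG
    M = sparse.diags(1.0 / A.diagonal())
    u, info = cg(A, b, rtol=min(rtol * 1e-2, 1e-10), atol=0.0, maxiter=20_000, M=M)
    if info != 0:
        u = spsolve(A.tocsc(), b)
    res = np.linalg.norm(A @ u - b)
    if res > rtol * max(np.linalg.norm(b), 1e-30):
        raise RuntimeError(f"linear solve residual {res:.3e} above tolerance")
    return u.reshape(shape)


def field_magnitude(u: np.ndarray, spacing) -> np.ndarray:
    """|∇u| in V/cm (central differences, one-sided at the boundary)."""
    grads = np.gradient(u, *spacing)  # V/mm
    return np.sqrt(sum(gr * gr for gr in grads)) * 10.0


def electrode_current(u: np.ndarray, sigma: np.ndarray,
                      electrode_labels: np.ndarray, needle: int,
                      spacing=(1.0, 1.0, 1.0)) -> float:
    """Net current (A) flowing out of one needle's conductor voxels."""
    elec = electrode_labels == needle + 1
    g = _face_conductances(sigma, spacing)
    total = 0.0
    for ax in range(3):
        e1 = np.moveaxis(elec, ax, 0)[:-1]
        e2 = np.moveaxis(elec, ax, 0)[1:]
        u1 = np.moveaxis(u, ax, 0)[:-1]
        u2 = np.moveaxis(u, ax, 0)[1:]
        gax = np.moveaxis(g[ax], ax, 0)
        out_faces = e1 & ~e2  # flux from electrode cell toward +ax neighbour
        total += float(np.sum(gax[out_faces] * (u1[out_faces] - u2[out_faces])))
        in_faces = ~e1 & e2  # flux from electrode cell toward -ax neighbour
        total += float(np.sum(gax[in_faces] * (u2[in_faces] - u1[in_faces])))
    return total


def solve_nonlinear_pair(sigma0_grid: np.ndarray, tissue_labels: np.ndarray,
                         electrode_labels: np.ndarray, pair: Tuple[int, int],
                         voltage: float, props: Dict[int, TissueProperties],
                         spacing=(1.0, 1.0, 1.0), tol: float = 1e-3,
                         max_iter: int = 20):
    """Fixed-point iteration of solve → field → conductivity update.

    The update ``σ ← max(σ, σ(E))`` is voxelwise nondecreasing and bounded
    by each tissue's σmax, so the iteration converges; it stops when the
    largest relative σ increase drops below ``tol`` or ``max_iter`` is hit
    (returning ``converged=False`` in that case, not raising).

    Returns ``(u, sigma, E, iterations, converged)``.
    """
    sigma = np.asarray(sigma0_grid, dtype=np.float64).copy()
    u = E = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        u = solve_pair(sigma, electrode_labels, pair, voltage, spacing)
        E = field_magnitude(u, spacing)
        sigma_new = np.maximum(sigma, sigma_of_E(E, tissue_labels, props))
        delta = np.max((sigma_new - sigma) / sigma)
        sigma = sigma_new
        if delta < tol:
            converged = True
            break
    return u, sigma, E, iterations, converged


def solve_sequence(tissue_labels: np.ndarray, electrode_labels: np.ndarray,
                   pairs: Sequence[Tuple[int, int]], voltages: Sequence[float],
                   props: Dict[int, TissueProperties], spacing=(1.0, 1.0, 1.0),
                   tol: float = 1e-3, max_iter: int = 20,
                   reset_sigma_per_pair: bool = False) -> FieldSolution:
    """Run the nonlinear solve over the whole pair sequence.

    Conductivity state is carried across pairs by default (electroporation
    within a session is treated as irreversible); ``reset_sigma_per_pair``
    restarts each pair from baseline. The cumulative field map is the
    voxelwise maximum of the per-pair fields.
    """
    if len(voltages) != len(pairs):
        raise ValueError("voltages list must match the pair sequence")
    base = sigma_of_E(np.zeros(tissue_labels.shape), tissue_labels, props)
    sigma = base.copy()
    potentials, fields, iters, flags = [], [], [], []
    cumulative = np.zeros(tissue_labels.shape)
    for pair, U in zip(pairs, voltages):
        start = base if reset_sigma_per_pair else sigma
        u, sigma_out, E, it, ok = solve_nonlinear_pair(
            start, tissue_labels, electrode_labels, pair, U, props,
            spacing, tol, max_iter,
        )
        if not reset_sigma_per_pair:
            sigma = sigma_out
        potentials.append(u)
        fields.append(E)
        iters.append(it)
        flags.append(ok)
        cumulative = np.maximum(cumulative, E)
    return FieldSolution(potentials, [float(v) for v in voltages], fields,
                         cumulative, sigma if not reset_sigma_per_pair else sigma_out,
                         iters, flags, tuple(spacing))
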