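"""16-electrode EIT forward model on the unit disc.

Adjacent-adjacent protocol: current is driven through each neighbouring
electrode pair in turn (16 drive pairs); for each drive, voltages are read
on every neighbouring pair that does not touch a driven electrode
(13 pairs), giving 16 x 13 = 208 measurements.

The forward map is linearized about a homogeneous reference conductivity:
a 2D finite-element solve (linear triangles, point electrodes) provides the
baseline voltages v0 and the sensitivity (Jacobian) matrix J via the
adjoint-field identity, after which boundary voltages for a phantom are
v = v0 + J (sigma - sigma_ref) on the pixel grid.  A full nonlinear FEM
re-solve is also exposed as an independent oracle for testing.

Measurement noise is additive Gaussian at a stated SNR; the drawn noise
vector is rescaled post-draw so the realized RMS ratio matches the request
exactly.  The SNR convention follows the amplitude-ratio form
SNR = 10 lg(RMS(V)/RMS(N)); the conventional power form (factor 20) is
available via ``snr_convention="power"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

from .phantoms import GRID_SIZE, LEG_RADIUS_PX, BACKGROUND_SIGMA, domain_mask

__all__ = [
    "ElectrodeProtocol", "SensitivityMatrix", "VoltageFrame", "DiscMesh",
    "build_protocol", "build_mesh", "build_sensitivity", "solve_forward",
    "add_noise", "noise_schedule", "nonlinear_forward", "NOISE_SCHEDULE",
]

N_ELECTRODES = 16
DRIVE_CURRENT = 1e-3  # ampere; nominal 1 mA drive


@dataclass(frozen=True)
class ElectrodeProtocol:
    n_electrodes: int
    drive_pairs: tuple              # 16 adjacent pairs
    measure_pairs: tuple            # per drive: 13 adjacent pairs

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for m in self.measure_pairs)

    def flat_pairs(self):
        """Canonical (drive_idx, measure_pair) enumeration, drive-major."""
        out = []
        for d, mlist in enumerate(self.measure_pairs):
            for m in mlist:
                out.append((d, m))
        return out

    def to_json(self) -> str:
        import json
        return json.dumps({
            "n_electrodes": self.n_electrodes,
            "drive_pairs": [list(p) for p in self.drive_pairs],
            "measure_pairs": [[list(p) for p in m]
                              for m in self.measure_pairs]})


def build_protocol(n_electrodes: int = N_ELECTRODES) -> ElectrodeProtocol:
    ne = n_electrodes
    drives = tuple((i, (i + 1) % ne) for i in range(ne))
    measures = []
    for a, b in drives:
        mlist = []
        for j in range(ne):
            pair = (j, (j + 1) % ne)
            if a in pair or b in pair:
                continue
            mlist.append(pair)
        measures.append(tuple(mlist))
    return ElectrodeProtocol(ne, drives, tuple(measures))


# ---------------------------------------------------------------------------
# mesh + FEM
# ---------------------------------------------------------------------------

@dataclass
class DiscMesh:
    nodes: np.ndarray        # (N, 2) coordinates on the unit disc
    tris: np.ndarray         # (T, 3) node indices
    electrode_nodes: np.ndarray   # (16,) node indices on the boundary
    areas: np.ndarray        # (T,)
    grads: np.ndarray        # (T, 3, 2) basis-function gradients


def build_mesh(n_boundary: int = 64, target_h: float = 0.09) -> DiscMesh:
    """Structured-ring Delaunay mesh of the unit disc.

    Electrodes sit on every ``n_boundary/16``-th boundary node so their
    angular positions are uniform.
    """
    pts = [np.column_stack([np.cos(2 * np.pi * np.arange(n_boundary) / n_boundary),
                            np.sin(2 * np.pi * np.arange(n_boundary) / n_boundary)])]
    n_rings = int(round(1.0 / target_h))
    for k in range(n_rings - 1, 0, -1):
        r = k / n_rings
        m = max(int(round(n_boundary * r)), 6)
        ang = 2 * np.pi * (np.arange(m) + 0.5 * (n_rings - k)) / m
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    pts.append(np.zeros((1, 2)))
    nodes = np.vstack(pts)
    tri = Delaunay(nodes)
    tris = tri.simplices

    # drop degenerate slivers (zero area)
    p = nodes[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    keep = areas > 1e-12
    tris, areas = tris[keep], areas[keep]
    p = nodes[tris]

    # linear basis gradients per element
    grads = np.empty((len(tris), 3, 2))
    for i in range(3):
        a, b = p[:, (i + 1) % 3], p[:, (i + 2) % 3]
        e = b - a
        # gradient of barycentric coordinate i: normal to opposite edge
        grads[:, i, 0] = -e[:, 1]
        grads[:, i, 1] = e[:, 0]
    grads /= (2 * areas)[:, None, None]
    # fix orientation so that grad_i . (p_i - a) = 1
    chk = np.einsum("tk,tk->t", grads[:, 0], p[:, 0] - p[:, 1])
    grads[chk < 0] *= -1.0

    step = n_boundary // N_ELECTRODES
    electrodes = np.arange(0, n_boundary, step)
    return DiscMesh(nodes, tris, electrodes, areas, grads)


def _stiffness(mesh: DiscMesh, sigma_elem: np.ndarray) -> sp.csc_matrix:
    t = len(mesh.tris)
    ke = np.einsum("tik,tjk->tij", mesh.grads, mesh.grads)  # (T,3,3)
    ke = ke * (mesh.areas * sigma_elem)[:, None, None]
    rows = np.repeat(mesh.tris, 3, axis=1).ravel()
    cols = np.tile(mesh.tris, (1, 3)).ravel()
    n = len(mesh.nodes)
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsc()
    return K


def _solve_patterns(mesh: DiscMesh, sigma_elem: np.ndarray,
                    protocol: ElectrodeProtocol) -> np.ndarray:
    """Node potentials for all 16 adjacent injection patterns; the
    potential is grounded at the center node (never an electrode)."""
    K = _stiffness(mesh, sigma_elem).tolil()
    n = len(mesh.nodes)
    gnd = n - 1  # mesh center node
    K[gnd, :] = 0.0
    K[gnd, gnd] = 1.0
    lu = spla.splu(K.tocsc())
    pots = np.empty((protocol.n_electrodes, n))
    for d, (a, b) in enumerate(protocol.drive_pairs):
        rhs = np.zeros(n)
        rhs[mesh.electrode_nodes[a]] += DRIVE_CURRENT
        rhs[mesh.electrode_nodes[b]] -= DRIVE_CURRENT
        rhs[gnd] = 0.0
        u = lu.solve(rhs)
        pots[d] = u
    return pots


def _measure(pots: np.ndarray, mesh: DiscMesh,
             protocol: ElectrodeProtocol) -> np.ndarray:
    v = np.empty(protocol.n_measurements)
    r = 0
    enodes = mesh.electrode_nodes
    for d, mlist in enumerate(protocol.measure_pairs):
        for (i, j) in mlist:
            v[r] = pots[d, enodes[i]] - pots[d, enodes[j]]
            r += 1
    return v


@dataclass
class SensitivityMatrix:
    J: np.ndarray            # (208, P) volts per (S/m), P in-domain pixels
    v0: np.ndarray           # (208,) baseline voltages
    mask: np.ndarray         # (64, 64) bool pixel domain
    pixel_index: np.ndarray  # (64, 64) int, -1 outside; column index inside
    reference: float
    protocol: ElectrodeProtocol
    mesh: DiscMesh
    grid_size: int


def build_sensitivity(grid_size: int = GRID_SIZE,
                      protocol: ElectrodeProtocol | None = None,
                      reference_conductivity: float = BACKGROUND_SIGMA,
                      mesh: DiscMesh | None = None) -> SensitivityMatrix:
    """Assemble J and v0 once at the homogeneous reference.

    J rows follow the canonical drive-major measurement order; columns are
    pixels inside the leg disc, in row-major pixel order.  Each pixel's
    sensitivity is the adjoint-field density -grad(u_d).grad(u_m)/I^2 of
    its containing element times the pixel area (in mesh units).
    """
    if reference_conductivity <= 0:
        raise ValueError("reference conductivity must be positive")
    protocol = protocol or build_protocol()
    mesh = mesh or build_mesh()
    sig = np.full(len(mesh.tris), reference_conductivity)
    pots = _solve_patterns(mesh, sig, protocol)
    v0 = _measure(pots, mesh, protocol)

    # element-wise field gradients per drive pattern: (16, T, 2)
    grads_u = np.empty((protocol.n_electrodes, len(mesh.tris), 2))
    for d in range(protocol.n_electrodes):
        ue = pots[d][mesh.tris]                      # (T, 3)
        grads_u[d] = np.einsum("ti,tik->tk", ue, mesh.grads)

    # pixel grid over the disc, mapped to the unit-circle mesh
    mask = domain_mask(grid_size, LEG_RADIUS_PX * grid_size / GRID_SIZE)
    c = (grid_size - 1) / 2.0
    scale = LEG_RADIUS_PX * grid_size / GRID_SIZE
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    px = (xx - c) / scale
    py = (yy - c) / scale
    pix_pts = np.column_stack([px[mask], py[mask]])
    tri_finder = Delaunay(mesh.nodes)
    simp = tri_finder.find_simplex(pix_pts * 0.999)
    # map Delaunay simplex ids back to kept-triangle ids by centroid match
    elem_of_pixel = _match_elements(mesh, tri_finder, simp)

    pixel_area = (1.0 / scale) ** 2
    # sensitivity rows
    rowmap = protocol.flat_pairs()
    drive_of_pair = {pair: d for d, pair in enumerate(protocol.drive_pairs)}
    J = np.empty((protocol.n_measurements, len(pix_pts)))
    for r, (d, mpair) in enumerate(rowmap):
        m = drive_of_pair[mpair]
        dens = -np.einsum("tk,tk->t", grads_u[d], grads_u[m]) / DRIVE_CURRENT ** 2
        J[r] = dens[elem_of_pixel] * pixel_area * DRIVE_CURRENT
    pixel_index = np.full((grid_size, grid_size), -1, dtype=np.int64)
    pixel_index[mask] = np.arange(mask.sum())
    return SensitivityMatrix(J=J, v0=v0, mask=mask, pixel_index=pixel_index,
                             reference=reference_conductivity,
                             protocol=protocol, mesh=mesh,
                             grid_size=grid_size)


def _match_elements(mesh: DiscMesh, tri_finder: Delaunay,
                    simp: np.ndarray) -> np.ndarray:
    """Map Delaunay simplex indices to indices into mesh.tris (which may
    have had slivers dropped)."""
    cent_kept = mesh.nodes[mesh.tris].mean(axis=1)
    cent_all = tri_finder.points[tri_finder.simplices].mean(axis=1)
    from scipy.spatial import cKDTree
    tree = cKDTree(cent_kept)
    _, nearest = tree.query(cent_all[simp])
    return nearest


@dataclass
class VoltageFrame:
    v: np.ndarray
    snr_db: float | None = None
    noise_seed: int | None = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=np.float64)


def solve_forward(sens: SensitivityMatrix, conductivity: np.ndarray) -> VoltageFrame:
    """Linearized forward solve v = v0 + J (sigma - ref) on in-domain pixels."""
    if conductivity.shape != (sens.grid_size, sens.grid_size):
        raise ValueError(
            f"conductivity shape {conductivity.shape} does not match "
            f"sensitivity grid {(sens.grid_size, sens.grid_size)}")
    delta = conductivity[sens.mask] - sens.reference
    return VoltageFrame(sens.v0 + sens.J @ delta)


def nonlinear_forward(sens: SensitivityMatrix,
                      conductivity: np.ndarray) -> VoltageFrame:
    """Independent oracle: re-assemble and solve the FEM with the phantom's
    conductivity sampled at element centroids."""
    mesh = sens.mesh
    cent = mesh.nodes[mesh.tris].mean(axis=1)
    c = (sens.grid_size - 1) / 2.0
    scale = LEG_RADIUS_PX * sens.grid_size / GRID_SIZE
    ix = np.clip(np.round(cent[:, 0] * scale + c).astype(int), 0, sens.grid_size - 1)
    iy = np.clip(np.round(cent[:, 1] * scale + c).astype(int), 0, sens.grid_size - 1)
    sigma_elem = conductivity[iy, ix]
    pots = _solve_patterns(mesh, sigma_elem, sens.protocol)
    return VoltageFrame(_measure(pots, mesh, sens.protocol))


def add_noise(frame: VoltageFrame, snr_db: float | None, seed: int,
              snr_convention: str = "amplitude") -> VoltageFrame:
    """Additive Gaussian noise, rescaled post-draw so the realized SNR is
    exact.  ``snr_db=None`` (or +inf) returns the frame unchanged."""
    if snr_db is None or np.isinf(snr_db):
        return VoltageFrame(frame.v.copy(), None, seed)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, frame.v.shape)
    rms_v = np.sqrt(np.mean(frame.v ** 2))
    factor = 10.0 if snr_convention == "amplitude" else 20.0
    target_rms_n = rms_v / (10.0 ** (snr_db / factor))
    noise *= target_rms_n / np.sqrt(np.mean(noise ** 2))
    return VoltageFrame(frame.v + noise, snr_db, seed)


NOISE_SCHEDULE: tuple = (None, 30.0, 45.0, 55.0)


def noise_schedule(sample_index: int):
    """Cyclic per-sample SNR tag: clean, 30, 45, 55 dB (period 4)."""
    if sample_index < 0:
        raise ValueError("sample index must be >= 0")
    return NOISE_SCHEDULE[sample_index % 4]
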