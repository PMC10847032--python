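"""Parametric head phantom: superellipsoid cranium with facial features.

The phantom stands in for a physical head phantom on a robotic arm.  It is a
triangulated superellipsoid (semi-axes LR x SI x AP) carrying a nose ridge,
brow/eye-socket depressions, chin and cheek features as smooth radial
displacement bumps, plus an optional seeded low-order surface roughness that
individualizes phantoms while staying reproducible.  Vertices carry anatomy
region labels used by the facial-deformation generator and by provenance
audits (e.g. which camera sees which cheek).

Axes follow the room convention: +x patient-left (LR), +y superior (SI),
+z anterior (AP); the face points toward +z.  Units mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = ["HeadPhantomParams", "HeadPhantom", "make_phantom", "REGION_CODES"]

REGION_CODES = {
    "cranium": 0,
    "forehead": 1,
    "nose": 2,
    "cheek_left": 3,
    "cheek_right": 4,
    "jaw": 5,
    "brow": 6,
    "larynx": 7,
}


@dataclass(frozen=True)
class HeadPhantomParams:
    """Feature amplitudes (mm) and overall shape of the phantom."""

    semi_axes: tuple[float, float, float] = (75.0, 105.0, 85.0)  # LR, SI, AP
    exponent: float = 2.2          # superellipsoid shape (2 = ellipsoid)
    nose_mm: float = 25.0          # nose ridge height
    brow_mm: float = 4.0           # eye-socket depression depth
    chin_mm: float = 6.0           # chin prominence
    cheek_mm: float = 3.0          # cheek fullness
    roughness_mm: float = 0.8      # seeded smooth random relief
    n_lat: int = 141               # latitude samples (odd: includes equator)
    n_lon: int = 140               # longitude samples (multiple of 4)

    def validate(self) -> None:
        for name, v, hi in [("nose_mm", self.nose_mm, 40.0),
                            ("brow_mm", self.brow_mm, 15.0),
                            ("chin_mm", self.chin_mm, 20.0),
                            ("cheek_mm", self.cheek_mm, 15.0),
                            ("roughness_mm", self.roughness_mm, 3.0)]:
            if not 0.0 <= v <= hi:
                raise ValueError(f"{name}={v} outside documented range [0, {hi}]")
        if self.exponent < 2.0 or self.exponent > 4.0:
            raise ValueError("exponent must be in [2, 4]")
        if min(self.semi_axes) <= 0 or max(self.semi_axes) > 200:
            raise ValueError("semi-axes must be positive and below 200 mm")
        if self.n_lat < 21 or self.n_lon < 20 or self.n_lon % 4:
            raise ValueError("grid too coarse or n_lon not a multiple of 4")


@dataclass
class HeadPhantom:
    vertices: np.ndarray       # (V, 3) mm, phantom-local frame
    faces: np.ndarray          # (F, 3) int
    labels: np.ndarray         # (V,) region codes
    params: HeadPhantomParams
    seed: int

    @property
    def mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def face_labels(self) -> np.ndarray:
        """Label of each triangle (first vertex wins)."""
        return self.labels[self.faces[:, 0]]

    def area_cm2(self) -> float:
        return float(self.mesh.area) / 100.0


def _signed_pow(w: np.ndarray, e: float) -> np.ndarray:
    return np.sign(w) * np.abs(w) ** e


def _bump(theta, phi, th0, ph0, s_th, s_ph):
    """Smooth Gaussian window in parameter space (angles in radians)."""
    dph = np.arctan2(np.sin(phi - ph0), np.cos(phi - ph0))  # wrap-safe
    return np.exp(-((theta - th0) / s_th) ** 2 - (dph / s_ph) ** 2)


def make_phantom(params: HeadPhantomParams | None = None,
                 seed: int = 0) -> HeadPhantom:
    """Deterministic head mesh for a given (params, seed)."""
    params = params or HeadPhantomParams()
    params.validate()
    a, b, c = params.semi_axes
    e = 2.0 / params.exponent

    th = np.linspace(-np.pi / 2, np.pi / 2, params.n_lat)
    ph = np.linspace(-np.pi, np.pi, params.n_lon, endpoint=False)
    theta, phi = np.meshgrid(th, ph, indexing="ij")

    ct = _signed_pow(np.cos(theta), e)
    x = a * ct * _signed_pow(np.cos(phi), e)
    z = c * ct * _signed_pow(np.sin(phi), e)
    y = b * _signed_pow(np.sin(theta), e)
    base = np.stack([x, y, z], axis=-1)

    d = np.radians  # readability below
    amp = np.zeros_like(theta)
    amp += params.nose_mm * _bump(theta, phi, d(-10), d(90), d(14), d(8))
    amp -= params.brow_mm * (_bump(theta, phi, d(12), d(76), d(7), d(7))
                             + _bump(theta, phi, d(12), d(104), d(7), d(7)))
    amp += params.chin_mm * _bump(theta, phi, d(-55), d(90), d(10), d(12))
    amp += params.cheek_mm * (_bump(theta, phi, d(-20), d(68), d(10), d(9))
                              + _bump(theta, phi, d(-20), d(112), d(10), d(9)))

    if params.roughness_mm > 0:
        rng = np.random.default_rng(seed)
        rough = np.zeros_like(theta)
        for k in range(1, 4):
            for m in range(0, 4):
                ca, sa = rng.normal(size=2)
                rough += (ca * np.cos(m * phi) + sa * np.sin(m * phi)) \
                    * np.cos(k * theta)
        rough *= params.roughness_mm / max(np.max(np.abs(rough)), 1e-12)
        amp += rough

    radial = base / np.maximum(np.linalg.norm(base, axis=-1, keepdims=True), 1e-9)
    verts = (base + amp[..., None] * radial).reshape(-1, 3)

    labels = _label_regions(theta, phi, verts.reshape(theta.shape + (3,)))

    faces = _grid_faces(params.n_lat, params.n_lon)
    return HeadPhantom(verts, faces, labels.reshape(-1), params, seed)


def _label_regions(theta: np.ndarray, phi: np.ndarray,
                   verts: np.ndarray) -> np.ndarray:
    d = np.degrees
    th, dph = d(theta), np.abs(d(np.arctan2(np.sin(phi - np.pi / 2),
                                            np.cos(phi - np.pi / 2))))
    lab = np.full(theta.shape, REGION_CODES["cranium"], dtype=np.int32)
    front = dph < 80
    lab[front & (th > 20) & (dph < 45)] = REGION_CODES["forehead"]
    lab[front & (th > 6) & (th <= 20) & (dph < 30)] = REGION_CODES["brow"]
    cheek = front & (th > -38) & (th <= 2) & (dph >= 13) & (dph < 42)
    lab[cheek & (verts[..., 0] > 0)] = REGION_CODES["cheek_left"]
    lab[cheek & (verts[..., 0] <= 0)] = REGION_CODES["cheek_right"]
    lab[front & (th > -70) & (th <= -38) & (dph < 40)] = REGION_CODES["jaw"]
    lab[front & (th <= -70)] = REGION_CODES["larynx"]
    # nose overrides its neighbors
    lab[front & (th > -32) & (th <= 6) & (dph < 13)] = REGION_CODES["nose"]
    return lab


def _grid_faces(n_lat: int, n_lon: int) -> np.ndarray:
    """Triangulate the (lat, lon) grid with longitude wrap-around."""
    idx = np.arange(n_lat * n_lon).reshape(n_lat, n_lon)
    nxt = np.roll(idx, -1, axis=1)  # longitude neighbor with wrap
    a = idx[:-1, :]
    b = nxt[:-1, :]
    cc = idx[1:, :]
    dd = nxt[1:, :]
    f1 = np.stack([a, b, cc], axis=-1).reshape(-1, 3)
    f2 = np.stack([b, dd, cc], axis=-1).reshape(-1, 3)
    return np.vstack([f1, f2]).astype(np.int64)
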