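"""Synthetic spherical-cap lung phantoms with analytic diaphragm index.

A phantom lung is a vertical cylinder of radius ``a`` whose caudal end
is a spherical cap of base radius ``a`` and height ``h``: the cap is the
cut of a sphere of radius ``R = (a^2 + h^2) / (2h)`` whose lateral
surface area is ``pi * (a^2 + h^2)`` over a base of area ``pi * a^2``.
The analytic diaphragm index of the cap is therefore

    index = (a^2 + h^2) / a^2 = 1 + (h / a)^2

— exactly 1 in the flat limit ``h = 0`` and 2 for a hemisphere
``h = a``. Real diaphragm domes sit in this range (COPD flattens the
dome toward 1), which makes the cap a ground-truth fixture for the whole
extraction-plus-index pipeline.

The cylinder body keeps the dome inside the lower third of the lung, as
in real anatomy (dome height is small against lung height), and keeps
mid-coronal cross-sections simply connected. Phantoms are deterministic;
optional surface roughening behind a seed perturbs the dome by ±1 voxel
per column for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .volume_io import LabelVolume

#: minimum lung-height-to-dome-height ratio keeping the dome inside the
#: lower third with margin
_MIN_HEIGHT_RATIO = 3.2


def analytic_cap_index(a: float, h: float) -> float:
    """Closed-form diaphragm index of a spherical cap: ``1 + (h/a)**2``."""
    if a <= 0:
        raise ParameterError(f"cap base radius must be > 0, got {a}")
    if not (0 <= h <= a):
        raise ParameterError(f"cap height must satisfy 0 <= h <= a, got {h}")
    return 1.0 + (h / a) ** 2


@dataclass
class LungSpec:
    """One phantom lung: cap geometry, position and its lobe labels."""

    side: str                          # "left" | "right"
    a: float                           # cap base radius, mm
    h: float                           # cap height, mm
    center: tuple[float, float]        # (cx, cy) of the lung axis, mm
    labels: tuple[int, ...]            # lobe labels to paint, caudal to cranial


@dataclass
class CapPhantomSpec:
    """Parameters of a one- or two-lung spherical-cap phantom.

    ``lung_height`` defaults to ``max(3.3 * max(h), 40)`` mm so the dome
    always lies inside the caudal third. The grid is sized
    automatically with a 2-voxel margin unless ``shape`` is given.
    """

    a: float = 60.0
    h: float = 30.0                    # left lung (and only lung if single)
    h_right: float | None = None       # None -> single (left) lung
    two_lungs: bool = False
    lung_height: float | None = None
    spacing: float = 1.0
    z_base: float = 5.0
    gap: float = 20.0                  # inter-lung gap, mm
    margin: float = 5.0
    labels_left: tuple[int, ...] = (1, 2)
    labels_right: tuple[int, ...] = (3, 4, 5)
    roughen_seed: int | None = None    # None -> smooth dome
    lungs: list[LungSpec] = field(default_factory=list, repr=False)
    shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.a <= 0 or self.spacing <= 0:
            raise ParameterError("a and spacing must be > 0")
        hs = [self.h] + ([self.h_right] if self.h_right is not None else [])
        for h in hs:
            if not (0 <= h <= self.a):
                raise ParameterError(f"need 0 <= h <= a, got h={h}, a={self.a}")
        if self.h_right is not None:
            self.two_lungs = True
        elif self.two_lungs:
            self.h_right = self.h
        h_max = max(self.h, self.h_right or 0.0)
        if self.lung_height is None:
            self.lung_height = max(_MIN_HEIGHT_RATIO * h_max * 1.05, 40.0)
        if h_max > 0 and self.lung_height < _MIN_HEIGHT_RATIO * h_max:
            raise ParameterError(
                f"lung_height {self.lung_height} must be >= "
                f"{_MIN_HEIGHT_RATIO} * h ({_MIN_HEIGHT_RATIO * h_max:.1f})"
            )
        if not self.lungs:
            cx_left = self.margin + self.a
            cy = self.margin + self.a
            self.lungs = [LungSpec(side="left", a=self.a, h=self.h,
                                   center=(cx_left, cy),
                                   labels=tuple(self.labels_left))]
            if self.two_lungs:
                cx_right = cx_left + 2 * self.a + self.gap
                self.lungs.append(LungSpec(side="right", a=self.a,
                                           h=self.h_right,
                                           center=(cx_right, cy),
                                           labels=tuple(self.labels_right)))
        if self.shape is None:
            x_extent = max(l.center[0] + l.a for l in self.lungs) + self.margin
            y_extent = max(l.center[1] + l.a for l in self.lungs) + self.margin
            z_extent = self.z_base + self.lung_height + self.margin
            self.shape = tuple(
                int(np.ceil(e / self.spacing)) + 1
                for e in (x_extent, y_extent, z_extent)
            )


def dome_height(spec_a: float, spec_h: float, rho: np.ndarray) -> np.ndarray:
    """Height of the cap surface above its base at lateral distance rho.

    ``dome(rho) = sqrt(R^2 - rho^2) - (R - h)`` with
    ``R = (a^2 + h^2) / (2h)``; identically 0 for a flat cap (h = 0).
    Only valid for rho <= a.
    """
    rho = np.asarray(rho, dtype=float)
    if spec_h == 0:
        return np.zeros_like(rho)
    R = (spec_a ** 2 + spec_h ** 2) / (2.0 * spec_h)
    return np.sqrt(np.maximum(R ** 2 - rho ** 2, 0.0)) - (R - spec_h)


def make_cap_phantom(spec: CapPhantomSpec) -> LabelVolume:
    """Voxelize the phantom onto its grid as a lobe label volume.

    A voxel (centre at ``index * spacing``) belongs to a lung when its
    lateral distance to the lung axis is <= a and its z lies between the
    dome surface and the flat lung top. Each lung's labels are painted
    in equal z-bands (caudal to cranial) so the lobe-to-lung merge has
    something to do.
    """
    nx, ny, nz = spec.shape
    s = spec.spacing
    x = np.arange(nx) * s
    y = np.arange(ny) * s
    z = np.arange(nz) * s
    grid = np.zeros((nx, ny, nz), dtype=np.uint8)
    rng = (np.random.default_rng(spec.roughen_seed)
           if spec.roughen_seed is not None else None)
    for lung in spec.lungs:
        cx, cy = lung.center
        rho = np.hypot(x[:, None] - cx, y[None, :] - cy)
        inside_xy = rho <= lung.a
        dome = spec.z_base + dome_height(lung.a, lung.h, rho)
        if rng is not None:
            dome = dome + rng.integers(-1, 2, size=dome.shape) * s
        top = spec.z_base + spec.lung_height
        zz = z[None, None, :]
        lung_mask = (inside_xy[:, :, None]
                     & (zz >= dome[:, :, None] - 1e-9)
                     & (zz <= top + 1e-9))
        # paint lobe labels in equal z-bands, caudal to cranial
        n_lab = len(lung.labels)
        edges = spec.z_base + spec.lung_height * np.arange(1, n_lab) / n_lab
        lab3d = np.full((nx, ny, nz), lung.labels[-1], dtype=np.uint8)
        band = np.searchsorted(edges, z, side="right")
        for k in range(nz):
            lab3d[:, :, k] = lung.labels[band[k]]
        grid[lung_mask] = lab3d[lung_mask]
    return LabelVolume(grid=grid, spacing=(s, s, s), origin=(0.0, 0.0, 0.0))
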