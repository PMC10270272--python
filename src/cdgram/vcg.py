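"""12-lead ECG to vectorcardiogram via the Kors regression transform.

The vectorcardiogram (VCG) represents cardiac electrical activity as one
spatial dipole with orthogonal components X (left), Y (inferior) and
Z (posterior).  The Kors regression matrix maps the 8 independent leads
(I, II, V1–V6) linearly onto (X, Y, Z); the derived leads (III, aVR, aVL,
aVF) carry no extra information and are ignored even when present.

The shipped coefficients are the standard Kors regression values.  They are
configuration, not a claim of this package: an alternative 3x8 matrix can be
loaded from CSV (rows X, Y, Z; columns I, II, V1..V6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError
from .io import ECGRecord, INDEPENDENT_LEADS

#: Kors regression coefficients, rows (X, Y, Z) x columns (I, II, V1..V6).
KORS_COEFFICIENTS = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
    ]
)


@dataclass
class KorsMatrix:
    """A 3x8 linear map from (I, II, V1..V6) to (X, Y, Z)."""

    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, 8):
            raise FormatError(
                f"transform matrix must be 3x8, got {self.coefficients.shape}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise FormatError("transform matrix has non-finite entries")

    @classmethod
    def default(cls) -> "KorsMatrix":
        return cls(KORS_COEFFICIENTS.copy())

    @classmethod
    def from_csv(cls, path: str) -> "KorsMatrix":
        return cls(np.loadtxt(path, delimiter=","))


@dataclass
class VCGRecord:
    """3-lead vector ECG (X, Y, Z) in mV at the source sampling rate."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise FormatError("X, Y, Z must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    def as_array(self) -> np.ndarray:
        """Stack to a (3, n_samples) array in X, Y, Z order."""
        return np.vstack([self.x, self.y, self.z])

    @property
    def magnitude(self) -> np.ndarray:
        """Spatial vector magnitude sqrt(X^2 + Y^2 + Z^2)."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


def kors_transform(rec: ECGRecord, m: KorsMatrix | None = None) -> VCGRecord:
    """Apply the lead-name-keyed linear transform; order in the file is irrelevant."""
    if m is None:
        m = KorsMatrix.default()
    stack = np.vstack([rec.lead(name) for name in INDEPENDENT_LEADS])
    xyz = m.coefficients @ stack
    return VCGRecord(xyz[0], xyz[1], xyz[2], rec.fs, rec.subject_id)
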