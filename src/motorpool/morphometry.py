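"""Covariance-ellipse morphometry of a motor-pool point cloud.

The scatter index (SI) quantifies how far a pool of labeled motor
neurons spreads in the coronal plane: fit the 2-D sample covariance of
the pooled (x, y) coordinates, take its two eigenvalues, and report

    SI = pi * lambda_1 * lambda_2

i.e. pi times the eigenvalue product — the area of the covariance
ellipse whose axes are the principal directions.  Directional
scattering is the plain standard deviation of the medio-lateral (x) and
dorso-ventral (y) coordinates separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .types import AlignedPool


@dataclass
class ScatterResult:
    """Covariance, eigenvalues, SI, directional SDs and ellipse of a pool.

    ``eigenvalues`` are the covariance eigenvalues (variances along the
    principal axes), sorted descending.  The ellipse semi-axes are their
    square roots — the directional standard deviations along the
    principal axes — so the drawn ellipse has width matched to the
    spread while the SI itself is the eigenvalue (variance) product.
    """

    cov_xx: float
    cov_yy: float
    cov_xy: float
    eigenvalues: np.ndarray        # (2,), lambda_1 >= lambda_2 >= 0
    si: float                      # pi * lambda_1 * lambda_2, units^2
    sd_ml: float                   # sqrt(cov_xx)
    sd_dv: float                   # sqrt(cov_yy)
    ellipse_center: np.ndarray     # (2,), the data mean
    ellipse_semi_axes: np.ndarray  # (2,), sqrt(eigenvalues)
    ellipse_angle: float           # radians, major axis vs +x
    n_neurons: int

    @property
    def cov(self) -> np.ndarray:
        return np.array(
            [[self.cov_xx, self.cov_xy], [self.cov_xy, self.cov_yy]]
        )


def _points(points) -> np.ndarray:
    if isinstance(points, AlignedPool):
        points = points.points
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def covariance2(points) -> np.ndarray:
    """Sample covariance (n-1 denominator) of a 2-D point cloud.

    Requires at least 3 points: below that the 2x2 covariance is rank
    deficient by construction and the scatter index undefined.
    """
    pts = _points(points)
    if pts.shape[0] < 3:
        raise InsufficientDataError(
            f"covariance needs >= 3 points, got {pts.shape[0]}"
        )
    return np.cov(pts, rowvar=False, ddof=1)


def directional_scatter(points) -> tuple[float, float]:
    """Sample SDs (n-1) of the medio-lateral and dorso-ventral coordinates."""
    pts = _points(points)
    if pts.shape[0] < 2:
        raise InsufficientDataError(
            f"directional scatter needs >= 2 points, got {pts.shape[0]}"
        )
    sd = pts.std(axis=0, ddof=1)
    return float(sd[0]), float(sd[1])


def scatter_index(points) -> ScatterResult:
    """Scatter index and covariance-ellipse parameters of a point cloud."""
    pts = _points(points)
    cov = covariance2(pts)
    # eigh returns ascending eigenvalues; clip tiny negatives from roundoff
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals[::-1], 0.0, None)
    major = evecs[:, ::-1][:, 0]
    si = float(np.pi * evals[0] * evals[1])
    return ScatterResult(
        cov_xx=float(cov[0, 0]),
        cov_yy=float(cov[1, 1]),
        cov_xy=float(cov[0, 1]),
        eigenvalues=evals,
        si=si,
        sd_ml=float(np.sqrt(cov[0, 0])),
        sd_dv=float(np.sqrt(cov[1, 1])),
        ellipse_center=pts.mean(axis=0),
        ellipse_semi_axes=np.sqrt(evals),
        ellipse_angle=float(np.arctan2(major[1], major[0])),
        n_neurons=pts.shape[0],
    )
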