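"""Lock-and-key infection kernels.

The adsorption coefficient theta_ij sets the rate at which phage strain j
attaches to (and instantly lyses) host strain i.  Under the relaxed scheme it
is a Gaussian function of the distance between the host resistance trait
h_hat and the phage infection trait v_hat,

    theta_ij = phi * exp(-s * (h_hat_i - v_hat_j)**2),

so phage are specialists whose host range narrows as the specificity ``s``
grows.  The strict scheme is the s -> infinity limit used by the equilibrium
theory: theta_ij = phi on an exact genetic match and 0 otherwise, decided by
bin-index equality (never floating-point trait comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .landscapes import DEFAULT_RHO, genotype_grid

SCHEMES = ("gaussian", "strict")


def _check_phi_s(phi: float, s: float | None = None) -> None:
    if not math.isfinite(phi) or phi <= 0:
        raise InvalidParameterError(f"phi must be finite and > 0, got {phi!r}")
    if s is not None and (not math.isfinite(s) or s < 0):
        raise InvalidParameterError(f"s must be finite and >= 0, got {s!r}")


def adsorption_gaussian(h_hat, v_hat, phi: float, s: float):
    """Relaxed lock-and-key kernel: phi * exp(-s * (h_hat - v_hat)**2)."""
    _check_phi_s(phi, s)
    h_hat = np.asarray(h_hat, dtype=float)
    v_hat = np.asarray(v_hat, dtype=float)
    out = phi * np.exp(-s * (h_hat - v_hat) ** 2)
    return float(out) if out.ndim == 0 else out


def adsorption_strict(h_bin, v_bin, phi: float):
    """Strict lock-and-key kernel: phi on bin-index equality, else 0."""
    _check_phi_s(phi)
    h_bin = np.asarray(h_bin)
    v_bin = np.asarray(v_bin)
    out = np.where(h_bin == v_bin, phi, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AdsorptionMatrix:
    """Pairwise adsorption coefficients for the current strain roster.

    ``theta[i, j]`` is the coefficient for phage strain j on host strain i.
    The matrix is rebuilt incrementally as strains are added or culled, but
    every incremental update is bit-identical to a full recomputation because
    the kernel is evaluated elementwise from the stored bins.
    """

    theta: np.ndarray          # shape (n_hosts, n_phages)
    host_bins: np.ndarray      # int bin indices, one per host strain
    phage_bins: np.ndarray
    phi: float
    s: float
    scheme: str
    rho: float = DEFAULT_RHO

    @classmethod
    def build(cls, host_bins, phage_bins, phi: float, s: float,
              scheme: str = "gaussian", rho: float = DEFAULT_RHO) -> "AdsorptionMatrix":
        """Construct the full matrix for the given rosters.

        Empty rosters are valid (phage-free runs give an n x 0 matrix whose
        lysis terms all vanish).
        """
        if scheme not in SCHEMES:
            raise InvalidParameterError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
        _check_phi_s(phi, s)
        host_bins = np.asarray(host_bins, dtype=np.int64)
        phage_bins = np.asarray(phage_bins, dtype=np.int64)
        theta = _kernel(host_bins[:, None], phage_bins[None, :], phi, s, scheme, rho)
        theta = theta.reshape(host_bins.size, phage_bins.size)
        return cls(theta=theta, host_bins=host_bins, phage_bins=phage_bins,
                   phi=phi, s=s, scheme=scheme, rho=rho)

    def with_host(self, h_bin: int) -> "AdsorptionMatrix":
        """Matrix extended by one host strain (new last row)."""
        row = _kernel(np.int64(h_bin), self.phage_bins, self.phi, self.s,
                      self.scheme, self.rho).reshape(1, -1)
        return AdsorptionMatrix(
            theta=np.vstack([self.theta, row]) if self.theta.size or row.size
            else np.zeros((self.theta.shape[0] + 1, 0)),
            host_bins=np.append(self.host_bins, h_bin),
            phage_bins=self.phage_bins,
            phi=self.phi, s=self.s, scheme=self.scheme, rho=self.rho)

    def with_phage(self, v_bin: int) -> "AdsorptionMatrix":
        """Matrix extended by one phage strain (new last column)."""
        col = _kernel(self.host_bins, np.int64(v_bin), self.phi, self.s,
                      self.scheme, self.rho).reshape(-1, 1)
        return AdsorptionMatrix(
            theta=np.hstack([self.theta, col]) if self.theta.size or col.size
            else np.zeros((0, self.theta.shape[1] + 1)),
            host_bins=self.host_bins,
            phage_bins=np.append(self.phage_bins, v_bin),
            phi=self.phi, s=self.s, scheme=self.scheme, rho=self.rho)

    def select(self, host_mask, phage_mask) -> "AdsorptionMatrix":
        """Matrix restricted to the surviving strains (after a cull)."""
        host_mask = np.asarray(host_mask, dtype=bool)
        phage_mask = np.asarray(phage_mask, dtype=bool)
        return AdsorptionMatrix(
            theta=self.theta[np.ix_(host_mask, phage_mask)],
            host_bins=self.host_bins[host_mask],
            phage_bins=self.phage_bins[phage_mask],
            phi=self.phi, s=self.s, scheme=self.scheme, rho=self.rho)

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape

    def to_dataframe(self):
        """Debug dump: long-format table (host_bin, phage_bin, theta)."""
        import pandas as pd

        hh, vv = np.meshgrid(self.host_bins, self.phage_bins, indexing="ij")
        return pd.DataFrame({
            "host_bin": hh.ravel(), "phage_bin": vv.ravel(),
            "theta": self.theta.ravel(),
        })


def build_matrix(host_bins, phage_bins, phi: float, s: float,
                 scheme: str = "gaussian", rho: float = DEFAULT_RHO) -> AdsorptionMatrix:
    """Functional alias for :meth:`AdsorptionMatrix.build`."""
    return AdsorptionMatrix.build(host_bins, phage_bins, phi, s, scheme, rho)


def _kernel(h_bins, v_bins, phi, s, scheme, rho):
    if scheme == "strict":
        return np.asarray(adsorption_strict(h_bins, v_bins, phi), dtype=float)
    grid_h = np.asarray(h_bins, dtype=float) * rho
    grid_v = np.asarray(v_bins, dtype=float) * rho
    return np.asarray(adsorption_gaussian(grid_h, grid_v, phi, s), dtype=float)
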