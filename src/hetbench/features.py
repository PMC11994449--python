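"""Data-intrinsic tumor features: sequencing power (NRPCC), copy-number burden
(PGA), clonal fraction, subclone CCF peak overlap, and VAF/CCF conversion.

NRPCC — the number of reads per chromosome copy, rho*d / (rho*Psi + 2(1-rho))
— rescales raw coverage d by purity rho and tumor ploidy Psi and is the
single best power proxy for single-sample subclonal reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from hetbench.core import GERMLINE, InvalidInputError, PhylogenyTruth

__all__ = [
    "CNASegment",
    "TumorFeatures",
    "nrpcc",
    "pga",
    "clonal_fraction",
    "peak_overlap",
    "vaf_to_ccf",
]


@dataclass(frozen=True)
class CNASegment:
    """One copy-number segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int
    clonal_fraction_of_segment: float = 1.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidInputError(f"segment end {self.end} < start {self.start}")
        if self.major < 0 or self.minor < 0:
            raise InvalidInputError("copy numbers must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_copies(self) -> int:
        return self.major + self.minor


@dataclass
class TumorFeatures:
    """Bag of per-tumor descriptors used in determinant analyses."""

    rho: float
    psi: float
    depth: float
    nrpcc: float
    pga: float | None = None
    cf: float | None = None
    m: int | None = None
    peak_overlap: float | None = None
    n_subclones: int | None = None
    wgd_status: bool | None = None
    topology: str | None = None


def nrpcc(rho: float, psi: float, depth: float) -> float:
    """Reads per chromosome copy: rho*d / (rho*Psi + 2*(1 - rho))."""
    if not (0.0 < rho <= 1.0):
        raise InvalidInputError(f"purity must lie in (0, 1], got {rho}")
    if psi <= 0:
        raise InvalidInputError(f"ploidy must be positive, got {psi}")
    if depth < 0:
        raise InvalidInputError(f"depth must be non-negative, got {depth}")
    return rho * depth / (rho * psi + 2.0 * (1.0 - rho))


def pga(segments: Sequence[CNASegment], ploidy: float, genome_size: int) -> float:
    """Fraction of the genome whose total copy number deviates from the
    (rounded) tumor ploidy.  Subclonal segments count their full length."""
    if genome_size <= 0:
        raise InvalidInputError("genome size must be positive")
    by_chrom: dict[str, list[CNASegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise InvalidInputError(
                    f"overlapping segments on {chrom}: [{a.start},{a.end}] and [{b.start},{b.end}]"
                )
    reference = round(ploidy)
    aberrant = sum(s.length for s in segments if s.total_copies != reference)
    return aberrant / genome_size


def clonal_fraction(truth: PhylogenyTruth) -> float:
    """Fraction of mutations assigned to the clonal (truncal) node."""
    total = sum(s.n_ssms for s in truth.subclones)
    if total == 0:
        raise InvalidInputError("no mutations in truth")
    clonal = next(s for s in truth.subclones if s.parent_id == GERMLINE)
    return clonal.n_ssms / total


def peak_overlap(
    subclone_ccfs: Sequence[np.ndarray],
    grid_size: int = 512,
    ccf_max: float = 1.25,
) -> float:
    """Fraction of CCF density space covered by more than one subclone.

    A Gaussian kernel density (Silverman bandwidth) is fitted per subclone on
    a shared CCF grid; the overlap is the trapezoidal integral of the
    second-largest density envelope over the integral of the summed
    densities.  A single subclone has no overlap (0); two subclones with
    identical CCF samples overlap maximally (0.5 of the total density).
    """
    if len(subclone_ccfs) == 0:
        raise InvalidInputError("no subclones provided")
    if len(subclone_ccfs) == 1:
        return 0.0
    grid = np.linspace(0.0, ccf_max, grid_size)
    densities = []
    for ccfs in subclone_ccfs:
        ccfs = np.asarray(ccfs, dtype=float)
        if ccfs.size < 2:
            raise InvalidInputError("each subclone needs >= 2 CCF values")
        if np.ptp(ccfs) < 1e-12:
            # degenerate sample: narrow Gaussian around the point mass
            d = np.exp(-0.5 * ((grid - ccfs[0]) / 0.01) ** 2)
        else:
            d = gaussian_kde(ccfs, bw_method="silverman")(grid)
        densities.append(d)
    dens = np.vstack(densities)
    dens_sorted = np.sort(dens, axis=0)[::-1]
    second = dens_sorted[1]
    total = dens.sum(axis=0)
    denom = np.trapezoid(total, grid)
    if denom <= 0:
        return 0.0
    return float(np.trapezoid(second, grid) / denom)


def vaf_to_ccf(
    vaf: float,
    rho: float,
    tumor_copies: int = 2,
    normal_copies: int = 2,
    multiplicity: int = 1,
) -> float:
    """Convert a variant allele fraction to a cancer cell fraction.

    CCF = vaf * (rho * C_tumor + (1 - rho) * C_normal) / (rho * multiplicity).
    """
    if multiplicity <= 0:
        raise InvalidInputError("multiplicity must be positive")
    denom = rho * multiplicity
    if denom <= 0:
        raise InvalidInputError("rho * multiplicity must be positive")
    return vaf * (rho * tumor_copies + (1.0 - rho) * normal_copies) / denom
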