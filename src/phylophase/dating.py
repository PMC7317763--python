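"""Four-fold degenerate (4D) site statistics and neutral-clock dating.

4D sites are third codon positions that can mutate to any nucleotide without
changing the encoded amino acid; they evolve approximately neutrally and
serve as a molecular clock.  Between a seed gene and its closest sister leaf
we count transitions and transversions at shared 4D sites, form the 4DTv
ratio (transversions over all substitutions — a slow, relative clock) and
the per-site divergence d4, and convert d4 to an absolute time with a neutral
substitution rate, halving for the parallel evolution of the two lineages
since their common ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import gaussian_kde

from .io import CodonAlignment, PhylomeError
from .csl import CSLRecord

log = logging.getLogger(__name__)


def _fourfold_prefixes() -> frozenset[str]:
    """Codon-family prefixes (first two bases) that are four-fold degenerate
    under the standard genetic code."""
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {table.forward_table.get(b1 + b2 + b3) for b3 in "ACGT"}
            if len(aas) == 1 and None not in aas:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


#: the 8 four-fold degenerate codon families of the standard genetic code
FOURFOLD_PREFIXES = _fourfold_prefixes()

_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})
_BASES = frozenset("ACGT")


@dataclass
class FourDSites:
    """0-based third-position column indices of shared 4D codons.

    ``informative`` sites have an unambiguous base in both rows and enter the
    substitution counts; ``ambiguous`` sites belong to a shared 4D family but
    carry a gap or N at the third position in at least one row.
    """

    informative: list[int]
    ambiguous: list[int]


@dataclass
class FourDStats:
    """Substitution counts at informative 4D sites between one sequence pair."""

    tree_id: str
    n_4d_sites: int
    ti: int
    tv: int

    @property
    def fourdtv(self) -> float | None:
        """Transversion fraction tv/(ti+tv); undefined without substitutions."""
        subs = self.ti + self.tv
        return self.tv / subs if subs >= 1 else None

    @property
    def d4(self) -> float | None:
        """Substitutions per 4D site; undefined when no 4D site is shared."""
        if self.n_4d_sites == 0:
            return None
        return (self.ti + self.tv) / self.n_4d_sites


@dataclass
class DatingConfig:
    """Neutral-clock parameters and ratio-retention filters.

    rate: neutral substitutions per position per generation (default 5e-9,
        in the range expected for plant nuclear genes).
    generations_per_year: 1 for an annual plant, making the rate per year.
    min_substitutions: minimum ti+tv for a 4DTv ratio to be retained.
    max_csl_distance_for_4dtv: cap on the seed-CSL tree distance
        (substitutions/site) for ratio and date retention; 0.05 by default,
        0.5 is the permissive alternative.
    """

    rate: float = 5e-9
    generations_per_year: float = 1.0
    min_substitutions: int = 5
    max_csl_distance_for_4dtv: float = 0.05
    peak_min_n: int = 10

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.min_substitutions < 1:
            raise ValueError("min_substitutions must be >= 1")


@dataclass
class DivergenceEstimate:
    """Seed-CSL divergence time for one tree, in million years (MyA)."""

    tree_id: str
    section: str
    time: float


def find_4d_sites(aln: CodonAlignment, a: str, b: str) -> FourDSites:
    """Locate shared four-fold degenerate sites between two aligned rows.

    A third-codon column is 4D iff in both rows the codon's first two
    positions are ungapped, non-N, identical between the rows, and form a
    four-fold degenerate family of the standard genetic code.  Third
    positions carrying a gap or N in either row are reported separately and
    excluded from substitution counting.
    """
    sa, sb = aln[a], aln[b]
    informative, ambiguous = [], []
    for start in range(0, aln.width, 3):
        pa, pb = sa[start:start + 2], sb[start:start + 2]
        if pa != pb or pa not in FOURFOLD_PREFIXES:
            continue
        ta, tb = sa[start + 2], sb[start + 2]
        if ta in _BASES and tb in _BASES:
            informative.append(start + 2)
        else:
            ambiguous.append(start + 2)
    return FourDSites(informative, ambiguous)


def count_4d_substitutions(aln: CodonAlignment, a: str, b: str,
                           tree_id: str = "") -> FourDStats:
    """Count transitions and transversions at informative 4D sites.

    A<->G and C<->T differences are transitions; every other difference is a
    transversion; identical sites still count toward the site total.  With
    zero shared 4D sites the stats are returned with d4 undefined (flagged by
    the caller).
    """
    sites = find_4d_sites(aln, a, b)
    sa, sb = aln[a], aln[b]
    ti = tv = 0
    for col in sites.informative:
        x, y = sa[col], sb[col]
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    stats = FourDStats(tree_id=tree_id, n_4d_sites=len(sites.informative),
                       ti=ti, tv=tv)
    if stats.n_4d_sites == 0:
        log.debug("%s: no shared 4D sites between %s and %s", tree_id, a, b)
    return stats


@dataclass
class RatioResult:
    value: float | None
    rejection_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.value is not None


def fourdtv_ratio(stats: FourDStats, rec: CSLRecord,
                  cfg: DatingConfig) -> RatioResult:
    """Retain the 4DTv ratio only for well-behaved seed-CSL pairs.

    The ratio is kept iff the pair accumulated at least
    ``cfg.min_substitutions`` substitutions and the seed-CSL tree distance is
    at most ``cfg.max_csl_distance_for_4dtv`` — excluding genes that evolve
    particularly slow or fast.
    """
    subs = stats.ti + stats.tv
    if subs < cfg.min_substitutions:
        return RatioResult(None, f"substitutions {subs} < {cfg.min_substitutions}")
    if rec.csl_distance > cfg.max_csl_distance_for_4dtv:
        return RatioResult(
            None,
            f"csl_distance {rec.csl_distance:.4f} > "
            f"{cfg.max_csl_distance_for_4dtv}")
    return RatioResult(stats.fourdtv)


def divergence_time(stats: FourDStats, cfg: DatingConfig,
                    section: str = "") -> DivergenceEstimate:
    """Convert d4 to an absolute divergence time in million years.

    time = d4 / (2 * rate * generations_per_year) / 1e6 — the factor 2
    accounts for the parallel evolution of seed and CSL since their common
    ancestor.  Undefined d4 raises; upstream retention filters match those of
    :func:`fourdtv_ratio`.
    """
    if stats.d4 is None:
        raise PhylomeError(f"{stats.tree_id}: d4 undefined (no 4D sites)")
    years = stats.d4 / (2.0 * cfg.rate * cfg.generations_per_year)
    return DivergenceEstimate(tree_id=stats.tree_id, section=section,
                              time=years / 1e6)


@dataclass
class PeakResult:
    """Headline mode of a divergence distribution plus its arithmetic mean."""

    peak: float
    mean: float
    n: int


def distribution_peak(values, min_n: int = 10) -> PeakResult:
    """Mode of a Gaussian KDE (Silverman bandwidth, 512-point grid) and mean.

    The KDE mode is the headline peak of the distribution; the arithmetic
    mean is reported alongside it.  Degenerate (zero-spread) samples return
    their common value directly.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < min_n:
        raise PhylomeError(
            f"need at least {min_n} values for a peak, got {vals.size}")
    mean = float(vals.mean())
    if np.ptp(vals) == 0.0:
        return PeakResult(peak=float(vals[0]), mean=mean, n=vals.size)
    kde = gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 512)
    peak = float(grid[np.argmax(kde(grid))])
    return PeakResult(peak=peak, mean=mean, n=vals.size)
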