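"""K-mer spectrum profiling of heterozygous diploid genomes.

A shotgun read set from a diploid individual yields a bimodal k-mer
multiplicity spectrum: k-mers overlapping a heterozygous site occur on
one haplotype only and peak at half the homozygous coverage.  The
spectrum above the error-noise cutoff is modelled as a two-component
negative-binomial mixture

    K(x) = s1 * NB(x; mean=mu,  size=size1) + s2 * NB(x; mean=2*mu, size=size2)

where ``mu`` is the coverage of the heterozygous peak, the homozygous
component is centred at exactly ``2*mu``, ``size`` is the usual
negative-binomial dispersion (variance = mean + mean^2/size) and
``s1, s2`` are non-negative scale factors proportional to the numbers of
distinct heterozygous/homozygous k-mers.  Summing the fitted component
densities gives those counts (H and D), from which the per-base
heterozygosity follows:

    rate = (H / (2k)) / (H/2 + D)

H is halved to express haploid content and divided by k because one
heterozygous base creates k distinct heterozygous k-mers (slightly
undercounting variants closer than k bases, hence a rate *range* in
practice).  ``H/2 + D`` is simultaneously the non-repetitive haploid
genome size in bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KmerHistogram", "MixtureFit", "HetEstimate", "FitError",
    "count_kmers", "fit_mixture", "component_sums", "heterozygosity",
    "genome_size", "model_spectrum",
]


@dataclass
class KmerHistogram:
    """Frequency spectrum of canonical k-mers: multiplicity -> # distinct k-mers."""

    k: int
    bins: dict[int, int]

    def __post_init__(self):
        if any(x < 1 or c < 0 for x, c in self.bins.items()):
            raise ValueError("multiplicities must be >=1 and counts >=0")
        self.bins = {int(x): int(c) for x, c in sorted(self.bins.items()) if c > 0}

    @property
    def total_distinct(self) -> int:
        return sum(self.bins.values())

    @property
    def total_kmers(self) -> int:
        return sum(x * c for x, c in self.bins.items())

    def arrays(self, lo: int = 1, hi: int | None = None):
        """Dense (x, count) arrays over [lo, hi]."""
        if not self.bins:
            return np.array([], dtype=int), np.array([], dtype=float)
        hi = hi if hi is not None else max(self.bins)
        xs = np.arange(lo, hi + 1)
        ys = np.array([self.bins.get(int(x), 0) for x in xs], dtype=float)
        return xs, ys

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for x, c in self.bins.items():
                fh.write(f"{x}\t{c}\n")

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerHistogram":
        """Read a two-column (multiplicity, count) table, the common
        k-mer-counter ``histo`` layout."""
        bins: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                x, c = line.split()[:2]
                bins[int(x)] = bins.get(int(x), 0) + int(float(c))
        return cls(k=k, bins=bins)


@dataclass
class MixtureFit:
    """Converged parameters of the two-component mixture."""

    mu: float
    size1: float
    size2: float
    s1: float
    s2: float
    fit_cutoff: int
    max_x: int
    residual_ss: float
    degenerate: bool = False  # s1 collapsed (effectively homozygous input)

    def density(self, xs: np.ndarray) -> np.ndarray:
        return model_spectrum(xs, self.mu, self.size1, self.size2, self.s1, self.s2)


@dataclass
class HetEstimate:
    rate: float
    H: float
    D: float
    k: int
    genome_size_nonrep: float


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# counting

def count_kmers(reads, k: int) -> KmerHistogram:
    """Count canonical k-mers of a read set into a multiplicity histogram.

    ``reads`` is an iterable of sequences or of (name, sequence) pairs.
    k must be odd (so no k-mer equals its own reverse complement) and in
    [3, 31] to fit a 2-bit encoding in 64 bits.  k-mers containing N are
    skipped.
    """
    if k % 2 == 0 or not 3 <= k <= 31:
        raise ValueError("k must be odd and within [3, 31]")
    from .seq import encode

    chunks = []
    for r in reads:
        s = r[1] if isinstance(r, tuple) else str(r)
        chunks.append(s)
        chunks.append("N")  # separator: windows crossing it are dropped
    if not chunks:
        return KmerHistogram(k=k, bins={})
    arr = encode("".join(chunks))
    if len(arr) < k:
        return KmerHistogram(k=k, bins={})

    n = len(arr) - k + 1
    a64 = (arr & 3).astype(np.uint64)
    # binary-doubling window codes: codes[w] holds the 2w-bit code of every
    # w-length window; combine power-of-two pieces to length k in O(log k)
    needed = {1 << b for b in range(6) if k & (1 << b)}
    codes = {1: a64}
    w = 1
    while 2 * w <= k:
        prev = codes[w]
        codes[2 * w] = (prev[:len(prev) - w] << np.uint64(2 * w)) | prev[w:]
        if w not in needed:
            del codes[w]
        w *= 2
    code = None
    pos = 0
    rem = k
    for w in sorted(codes, reverse=True):
        while rem >= w:
            piece = codes[w][pos:pos + n]
            if code is None:
                code = piece.copy()
            else:
                np.left_shift(code, np.uint64(2 * w), out=code)
                code |= piece
            pos += w
            rem -= w
    del codes, a64
    tmp = np.empty(n, dtype=np.uint64)
    # reverse complement of every window in O(1) passes: complement the
    # 2-bit codes, reverse the 2-bit groups (byteswap + per-byte table),
    # then right-align to 2k bits
    mask = np.uint64((1 << (2 * k)) - 1)
    np.bitwise_not(code, out=tmp)
    tmp &= mask
    rc = _REV2[tmp.byteswap().view(np.uint8)].view(np.uint64)
    rc >>= np.uint64(64 - 2 * k)
    canon = np.minimum(code, rc)
    del tmp, rc
    bad = (arr >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    canon = canon[(cs[k:] - cs[:-k]) == 0]  # drop windows containing N
    if canon.size == 0:
        return KmerHistogram(k=k, bins={})
    canon.sort()
    boundaries = np.flatnonzero(np.diff(canon)) + 1
    starts = np.concatenate(([0], boundaries, [canon.size]))
    spectrum = np.bincount(np.diff(starts))
    return KmerHistogram(k=k, bins={int(x): int(c)
                                    for x, c in enumerate(spectrum) if x > 0 and c > 0})


def _make_rev2() -> np.ndarray:
    """Lookup table reversing the four 2-bit groups within a byte."""
    b = np.arange(256, dtype=np.uint64)
    return (((b & 0x03) << 6) | ((b & 0x0C) << 2)
            | ((b & 0x30) >> 2) | ((b & 0xC0) >> 6)).astype(np.uint8)


_REV2 = _make_rev2()


# ---------------------------------------------------------------------------
# mixture model

def _nb_pmf(x, mean, size):
    # scipy parameterizes NB by (n, p) with mean = n(1-p)/p -> p = n/(n+mean)
    return stats.nbinom.pmf(x, size, size / (size + mean))


def model_spectrum(xs, mu, size1, size2, s1, s2) -> np.ndarray:
    """Evaluate the mixture density K(x) at multiplicities ``xs``."""
    xs = np.asarray(xs)
    return s1 * _nb_pmf(xs, mu, size1) + s2 * _nb_pmf(xs, 2.0 * mu, size2)


def default_fit_cutoff(hist: KmerHistogram, floor: int = 3) -> int:
    """First local minimum of the window-3 smoothed spectrum (>= floor).

    The trough between the error noise at low multiplicity and the
    heterozygous peak is the natural lower bound of the fit range.
    """
    xs, ys = hist.arrays()
    if len(ys) < 3:
        return floor
    sm = np.convolve(ys, np.ones(3) / 3.0, mode="same")
    peak = int(np.argmax(sm))
    for i in range(1, peak):  # the trough sits before the main peak
        if int(xs[i]) < floor:
            continue
        if sm[i] <= sm[i - 1] and sm[i] <= sm[i + 1]:
            return int(xs[i])
    return floor


def _initial_mu(xs, ys):
    """Peak coverage guess: halve the argmax when a secondary peak sits
    near half of it (argmax then being the homozygous peak)."""
    if len(ys) == 0 or ys.max() <= 0:
        raise FitError("no mass above the fit cutoff")
    sm = np.convolve(ys, np.ones(3) / 3.0, mode="same") if len(ys) >= 3 else ys
    peak_x = float(xs[int(np.argmax(sm))])
    half = peak_x / 2.0
    lo = np.searchsorted(xs, half * 0.7)
    hi = np.searchsorted(xs, half * 1.3) + 1
    if hi - lo >= 1 and lo < len(xs):
        seg = sm[lo:hi]
        if seg.size and seg.max() > 0.05 * sm.max():
            # local maximum inside the half-coverage window?
            j = lo + int(np.argmax(seg))
            if 0 < j < len(sm) - 1 and sm[j] >= sm[j - 1] and sm[j] >= sm[j + 1]:
                return half if half > 1 else peak_x
    return peak_x


def fit_mixture(hist: KmerHistogram, fit_cutoff: int | None = None,
                max_x: int | None = None, max_restarts: int = 5,
                seed: int = 0) -> MixtureFit:
    """Nonlinear least-squares fit of the mixture to the spectrum.

    The fit range is [fit_cutoff, max_x]; the cutoff defaults to the
    spectrum's error trough (:func:`default_fit_cutoff`) and the upper
    bound to four times the initial peak guess, excluding repetitive
    k-mers the two-component model does not describe.  Up to
    ``max_restarts`` jittered restarts are attempted on failure.
    """
    if fit_cutoff is None:
        fit_cutoff = default_fit_cutoff(hist)
    xs_all, ys_all = hist.arrays(lo=fit_cutoff)
    if len(xs_all) == 0 or ys_all.sum() == 0:
        raise FitError("empty histogram above the fit cutoff")
    mu0 = _initial_mu(xs_all, ys_all)
    if max_x is None:
        max_x = int(np.ceil(4 * mu0))
    keep = xs_all <= max_x
    xs, ys = xs_all[keep], ys_all[keep]
    if len(xs) < 5:
        raise FitError("fewer than 5 spectrum bins in the fit range")

    def scales_for(mu, size1, size2):
        """Optimal non-negative (s1, s2) given shape params (model is linear in them)."""
        A = np.column_stack([_nb_pmf(xs, mu, size1), _nb_pmf(xs, 2 * mu, size2)])
        try:
            s, _ = optimize.nnls(A, ys)
        except RuntimeError:
            s = np.array([ys.max(), ys.max()])
        return np.maximum(s, 0.0)

    def residuals(theta):
        mu, ls1, ls2, s1, s2 = theta
        return model_spectrum(xs, mu, np.exp(ls1), np.exp(ls2), s1, s2) - ys

    rng = np.random.default_rng(seed)
    # two deterministic hypotheses — the spectrum's main peak is either the
    # heterozygous component (mu0) or the homozygous one (mu0/2); a shallow
    # half-coverage shoulder makes the peak-detection heuristic unreliable,
    # so both are always tried, followed by jittered restarts.
    starts = [(mu0, 5.0), (mu0 / 2.0, 5.0)]
    starts += [(mu0 * float(rng.uniform(0.4, 1.2)), float(rng.uniform(2.0, 20.0)))
               for _ in range(max_restarts)]
    best = None
    last_res = np.inf
    for attempt, (mu_i, size_i) in enumerate(starts):
        mu_i = min(max(mu_i, fit_cutoff + 0.5), max_x - 0.5)
        s1_i, s2_i = scales_for(mu_i, size_i, size_i)
        theta0 = np.array([mu_i, np.log(size_i), np.log(size_i), s1_i, s2_i])
        init_ss = float(np.sum(residuals(theta0) ** 2))
        try:
            res = optimize.least_squares(
                residuals, theta0,
                bounds=([fit_cutoff, np.log(1e-2), np.log(1e-2), 0.0, 0.0],
                        [max_x, np.log(1e4), np.log(1e4), np.inf, np.inf]),
                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=500 * 5)
        except Exception:
            continue
        ss = float(np.sum(res.fun ** 2))
        last_res = ss
        if res.success and ss <= init_ss and (best is None or ss < best[0]):
            best = (ss, res.x)
        # jittered restarts are only needed when both deterministic
        # hypotheses leave visible structure unexplained
        if attempt >= 1 and best is not None \
                and best[0] < 1e-4 * float(np.sum(ys ** 2)):
            break
    if best is None:
        raise FitError(f"mixture fit did not converge; last residual SS {last_res:.3g}")
    ss, (mu, ls1, ls2, s1, s2) = best
    h_mass = s1 * _nb_pmf(xs, mu, np.exp(ls1)).sum()
    d_mass = s2 * _nb_pmf(xs, 2 * mu, np.exp(ls2)).sum()
    total_mass = h_mass + d_mass
    if total_mass > 0 and h_mass > 0.95 * total_mass:
        # A fit dominated by the heterozygous component would imply a
        # heterozygosity near 1/k — not a diploid spectrum.  A unimodal
        # (homozygous) spectrum has landed in component 1; re-express the
        # single peak as the homozygous component at 2*mu.
        mu, ls2, s2, s1 = mu / 2.0, ls1, s1, 0.0
        ss = float(np.sum((model_spectrum(xs, mu, np.exp(ls1), np.exp(ls2),
                                          s1, s2) - ys) ** 2))
    total = s1 + s2
    degenerate = bool(total > 0 and (s1 / total) < 1e-4 or s1 == 0.0)
    return MixtureFit(mu=float(mu), size1=float(np.exp(ls1)), size2=float(np.exp(ls2)),
                      s1=float(s1), s2=float(s2), fit_cutoff=int(fit_cutoff),
                      max_x=int(max_x), residual_ss=ss, degenerate=degenerate)


def component_sums(fit: MixtureFit, hist: KmerHistogram) -> tuple[float, float]:
    """Numbers of heterozygous (H) and homozygous (D) non-repetitive
    k-mers: the fitted component densities summed over the fit range."""
    xs = np.arange(fit.fit_cutoff, fit.max_x + 1)
    H = float(fit.s1 * _nb_pmf(xs, fit.mu, fit.size1).sum())
    D = float(fit.s2 * _nb_pmf(xs, 2 * fit.mu, fit.size2).sum())
    return H, D


def heterozygosity(H: float, D: float, k: int) -> HetEstimate:
    """Per-base heterozygosity from heterozygous/homozygous k-mer counts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if H < 0 or D < 0:
        raise ValueError("H and D must be non-negative")
    if H == 0 and D == 0:
        raise ValueError("heterozygosity undefined for H = D = 0")
    denom = H / 2.0 + D
    rate = (H / (2.0 * k)) / denom
    return HetEstimate(rate=rate, H=H, D=D, k=k, genome_size_nonrep=denom)


def genome_size(fit: MixtureFit, hist: KmerHistogram) -> tuple[float, float]:
    """(non-repetitive size, total size) estimates in bases.

    The non-repetitive haploid size is H/2 + D.  The total estimate
    divides all k-mer observations above the cutoff (repeats included)
    by the homozygous coverage 2*mu.
    """
    H, D = component_sums(fit, hist)
    nonrep = H / 2.0 + D
    obs = sum(x * c for x, c in hist.bins.items() if x >= fit.fit_cutoff)
    if obs == 0:
        raise FitError("no k-mer observations above the fit cutoff")
    return nonrep, obs / (2.0 * fit.mu)
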