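"""Multi-scale running-window significance of contacts (domainograms).

Coverage of analyzable fragment ends is binarized (captured at least once or
not), a compartment-wide background coverage rate pi is estimated, and each
running window of w consecutive analyzable ends is scored with the binomial
upper-tail probability of observing at least its number of covered ends at
rate pi.  The resulting p-value matrix over (window size x position) is the
domainogram, rendered on a 1 .. 1e-10 colour scale; interacting domains are
then called at one window size under Benjamini-Hochberg FDR control and
merged into genomic intervals, separately for far-cis and trans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .alleleseq import CaptureTable, ViewpointSpec
from .fragmentome import FragmentEndDB

#: p-values are floored here for display only; raw values are retained
DISPLAY_FLOOR = 1e-10
#: default mask radius around the viewpoint, in fragments (~1 Mb at the
#: expected 4 kb fragment spacing): near-cis polymer decay saturates
#: coverage and would swamp the background estimate
DEFAULT_EXCLUSION_RADIUS = 244
DEFAULT_WINDOW_SIZES = (1, 2, 3, 5, 8, 12, 21, 30, 50)


@dataclass
class BinaryCoverage:
    """Binarized capture coverage over the analyzable ends of one compartment."""

    compartment: str  # 'cis' | 'trans'
    positions: pd.DataFrame  # end_id, chrom, start, end
    covered: np.ndarray  # bool
    pi: float

    @property
    def n(self) -> int:
        return len(self.covered)


def binarize(
    table: CaptureTable,
    vp: ViewpointSpec,
    db: Optional[FragmentEndDB] = None,
    exclusion_radius: int = DEFAULT_EXCLUSION_RADIUS,
) -> dict[str, BinaryCoverage]:
    """Binary coverage and background rate pi, per compartment.

    An end is covered iff its raw count is >= 1.  Cis ends within
    ``exclusion_radius`` fragments of the viewpoint are masked out; pi is
    the covered fraction computed separately for far-cis and trans.
    """
    if exclusion_radius < 0:
        raise ValueError("exclusion_radius must be >= 0")
    db = db if db is not None else table.db
    if db is None:
        raise ValueError("a fragment-end database is required")
    vp_frag = db.fragment_map.frag_id_at(vp.chrom, vp.pos)
    ends = db.ends
    analyzable = db.analyzable
    frag_ids = ends["frag_id"].to_numpy()
    chroms = ends["chrom"].to_numpy()
    covered_all = table.counts >= 1

    out = {}
    cis_sel = analyzable & (chroms == vp.chrom) & (
        np.abs(frag_ids - vp_frag) > exclusion_radius
    )
    trans_sel = analyzable & (chroms != vp.chrom)
    for name, sel in (("cis", cis_sel), ("trans", trans_sel)):
        pos = ends.loc[sel, ["end_id", "chrom", "start", "end"]].reset_index(drop=True)
        cov = covered_all[sel]
        pi = float(cov.mean()) if len(cov) else 0.0
        out[name] = BinaryCoverage(name, pos, cov, pi)
    return out


@dataclass
class Domainogram:
    """p-value matrix over (window size x analyzable-end position)."""

    window_sizes: np.ndarray
    P: np.ndarray  # shape (len(window_sizes), n positions); raw p in (0, 1]
    positions: pd.DataFrame
    pi: float
    compartment: str = ""

    def display(self) -> np.ndarray:
        """The matrix floored at the rendering scale (P = 1 .. 1e-10)."""
        return np.maximum(self.P, DISPLAY_FLOOR)

    def row(self, w: int) -> np.ndarray:
        idx = np.nonzero(self.window_sizes == w)[0]
        if len(idx) == 0:
            raise KeyError(f"window size {w} not in the domainogram")
        return self.P[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        """Long format (chrom, start, end, w, p) for export."""
        rows = []
        for wi, w in enumerate(self.window_sizes):
            df = self.positions[["chrom", "start", "end"]].copy()
            df["w"] = int(w)
            df["p"] = self.P[wi]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def plot(self, ax=None):
        """Heatmap of -log10 p, window size on the Y axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        img = -np.log10(self.display())
        ax.imshow(
            img, aspect="auto", origin="lower", cmap="inferno",
            vmin=0, vmax=-np.log10(DISPLAY_FLOOR),
            extent=[0, img.shape[1], -0.5, len(self.window_sizes) - 0.5],
        )
        ax.set_yticks(range(len(self.window_sizes)))
        ax.set_yticklabels([str(int(w)) for w in self.window_sizes])
        ax.set_ylabel("window size")
        ax.set_xlabel(f"{self.compartment} fragment ends")
        return ax


def _window_counts(covered: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Covered count and actual size of the centered window at every position."""
    n = len(covered)
    c = np.concatenate([[0], np.cumsum(covered.astype(np.int64))])
    idx = np.arange(n)
    half = (w - 1) // 2
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + (w - half))
    return c[hi] - c[lo], hi - lo


def window_significance(
    coverage: BinaryCoverage | np.ndarray,
    pi: Optional[float] = None,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
) -> Domainogram:
    """Binomial upper-tail p-values for running windows of covered ends.

    ``P[w, i]`` is the probability of >= k covered ends among the m ends of
    the window of nominal size w centered at i (m < w near the edges),
    under i.i.d. coverage at rate pi.  Windows advance over analyzable ends
    only, so mappability holes cannot masquerade as depletion.
    """
    if isinstance(coverage, BinaryCoverage):
        covered = coverage.covered
        pi = coverage.pi if pi is None else pi
        positions = coverage.positions
        compartment = coverage.compartment
    else:
        covered = np.asarray(coverage, dtype=bool)
        if pi is None:
            raise ValueError("pi is required for a bare coverage vector")
        idx = np.arange(len(covered))
        positions = pd.DataFrame(
            {"end_id": idx, "chrom": "vec", "start": idx, "end": idx + 1}
        )
        compartment = ""
    W = np.asarray(sorted(set(int(w) for w in window_sizes)))
    n = len(covered)
    if n and W.max() > n:
        raise ValueError("largest window exceeds the number of analyzable ends")
    P = np.ones((len(W), n))
    if pi <= 0.0 or pi >= 1.0:
        warnings.warn(
            f"degenerate background coverage pi={pi}; all p-values set to 1"
        )
        return Domainogram(W, P, positions, float(pi), compartment)
    for wi, w in enumerate(W):
        k, m = _window_counts(covered, int(w))
        P[wi] = binom.sf(k - 1, m, pi)
    return Domainogram(W, P, positions, float(pi), compartment)


def null_calibration(
    pi: float,
    window_sizes: Sequence[int],
    n_ends: int,
    n_sims: int,
    seed: int,
    alphas: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Empirical false-positive rates of the window model under its own null.

    Simulates i.i.d. Bernoulli(pi) coverage, scores full-size windows, and
    reports per (w, alpha) the fraction of windows with p < alpha together
    with its Monte-Carlo standard error and the exact discrete tail mass
    P(p < alpha).  Because p is discrete the empirical rate is conservative
    (<= alpha).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    X = rng.random((n_sims, n_ends)) < pi
    c = np.concatenate([np.zeros((n_sims, 1), dtype=np.int64), np.cumsum(X, axis=1)], axis=1)
    rows = []
    for w in window_sizes:
        w = int(w)
        if w > n_ends:
            raise ValueError("window exceeds n_ends")
        k = c[:, w:] - c[:, :-w]  # full-size windows only
        sf_table = binom.sf(np.arange(w + 1) - 1, w, pi)
        p = sf_table[k]
        for alpha in alphas:
            per_sim = (p < alpha).mean(axis=1)
            below = np.nonzero(sf_table < alpha)[0]
            exact = float(sf_table[below[0]]) if len(below) else 0.0
            rows.append(
                {
                    "pi": pi,
                    "w": w,
                    "alpha": alpha,
                    "empirical_fpr": float(per_sim.mean()),
                    "mc_se": float(per_sim.std(ddof=1) / np.sqrt(n_sims)),
                    "exact_rate": exact,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class InteractingDomains:
    """Genomic intervals called significant at one window size, plus complement."""

    intervals: pd.DataFrame  # chrom, start, end
    complement: pd.DataFrame  # chrom, start, end
    compartment: str
    w_call: int
    fdr: float

    @property
    def n_domains(self) -> int:
        return len(self.intervals)

    def to_bed(self, path: str | Path, which: str = "intervals") -> None:
        getattr(self, which)[["chrom", "start", "end"]].to_csv(
            path, sep="\t", index=False, header=False
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def call_domains(
    dg: Domainogram, w_call: int = 50, fdr: float = 0.05
) -> InteractingDomains:
    """Benjamini-Hochberg domain calling at window size ``w_call``.

    Significant positions are merged into maximal runs and converted to
    genomic intervals via the fragment-end coordinates; the complement is
    the remainder of the analyzable territory of the compartment.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    p = dg.row(w_call)
    pos = dg.positions
    intervals: list[tuple[str, int, int]] = []
    if len(p):
        reject = multipletests(p, alpha=fdr, method="fdr_bh")[0]
        chroms = pos["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            sel = np.nonzero(chroms == chrom)[0]
            for a, b in _runs(reject[sel]):
                intervals.append(
                    (chrom, int(pos["start"].iloc[sel[a]]), int(pos["end"].iloc[sel[b]]))
                )
    # complement over the analyzable territory, per chromosome
    complement: list[tuple[str, int, int]] = []
    for chrom in pd.unique(pos["chrom"].to_numpy()) if len(pos) else []:
        sub = pos[pos["chrom"] == chrom]
        lo, hi = int(sub["start"].min()), int(sub["end"].max())
        cursor = lo
        for c, s, e in sorted(i for i in intervals if i[0] == chrom):
            if s > cursor:
                complement.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < hi:
            complement.append((chrom, cursor, hi))
    return InteractingDomains(
        intervals=pd.DataFrame(intervals, columns=["chrom", "start", "end"]),
        complement=pd.DataFrame(complement, columns=["chrom", "start", "end"]),
        compartment=dg.compartment,
        w_call=int(w_call),
        fdr=float(fdr),
    )
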