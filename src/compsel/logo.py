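"""Positional frequency matrices and information-content sequence logos.

Implements the classical information-content logo: at each position the
information content is ``IC = log2(20) - H(p)`` bits, where H is the
Shannon entropy of the amino-acid frequencies (stop excluded and the
remaining frequencies renormalized), optionally reduced by the
small-sample correction ``e(n) = 19 / (2 ln2 n)``.  Letter heights are
``frequency x IC``, so heights at a position sum to that position's IC.
With a non-uniform background (e.g. the amino-acid distribution an NNK
codon synthesizes), the information content is instead the relative
entropy to that background, which visualizes selection over synthesis
bias.  Error bars are standard deviations over a seeded bootstrap of the
motif set; numeric outputs never depend on the plotting layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import AA_LETTERS, STOP

__all__ = [
    "ALPHABET",
    "PositionalFrequencyMatrix",
    "LogoData",
    "frequency_matrix",
    "information_content",
    "bootstrap_sd",
    "uniform_background",
    "write_matrix_tsv",
    "plot_logo",
]

ALPHABET = AA_LETTERS + STOP  # 20 amino acids + stop, column order
_N_AA = len(AA_LETTERS)


@dataclass
class PositionalFrequencyMatrix:
    """Per-position letter frequencies over ``ALPHABET`` (21 columns)."""

    freqs: np.ndarray  # (length, 21), rows sum to 1
    n_sequences: int
    weighting: str  # 'unweighted' | 'read-weighted'

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(ALPHABET):
            raise ValueError(f"freqs must be (length, {len(ALPHABET)})")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("position frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, columns=list(ALPHABET),
                            index=pd.RangeIndex(self.length, name="position"))


@dataclass
class LogoData:
    """Information content, letter heights and bootstrap SDs, all in bits.

    ``heights`` and ``height_sd`` are (length, 20) over the amino-acid
    letters; positions whose content is entirely stop codons are undefined
    and reported as NaN.
    """

    information: np.ndarray          # (length,)
    heights: np.ndarray              # (length, 20)
    height_sd: np.ndarray | None     # (length, 20) or None
    background: np.ndarray           # (20,)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=list(AA_LETTERS),
                          index=pd.RangeIndex(len(self.information), name="position"))
        df.insert(0, "information", self.information)
        return df


def uniform_background() -> np.ndarray:
    return np.full(_N_AA, 1.0 / _N_AA)


def _validate_motifs(motifs: Sequence[str]) -> int:
    if not motifs:
        raise ValueError("motif set is empty")
    length = len(motifs[0])
    bad = [m for m in motifs if len(m) != length]
    if bad:
        raise ValueError(f"motifs of mixed length (expected {length}): {bad[:5]}")
    return length


def frequency_matrix(motifs: Sequence[str],
                     weights: Sequence[float] | None = None) -> PositionalFrequencyMatrix:
    """Positional frequency matrix of an equal-length motif set.

    Without weights, each *unique* motif counts once (a ranked top-k list is
    treated as a sequence set).  With weights (e.g. read counts, one per
    motif), occurrences are weighted instead.
    """
    motifs = [m.replace("/", "") for m in motifs]
    length = _validate_motifs(motifs)
    if weights is not None:
        if len(weights) != len(motifs):
            raise ValueError("weights must have the same cardinality as motifs")
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        items = list(zip(motifs, w))
        weighting = "read-weighted"
        n_seq = len(motifs)
    else:
        items = [(m, 1.0) for m in dict.fromkeys(motifs)]
        weighting = "unweighted"
        n_seq = len(items)

    col = {ch: i for i, ch in enumerate(ALPHABET)}
    freqs = np.zeros((length, len(ALPHABET)))
    for motif, wt in items:
        for pos, ch in enumerate(motif):
            try:
                freqs[pos, col[ch]] += wt
            except KeyError:
                raise ValueError(f"invalid letter {ch!r} in motif {motif!r}") from None
    totals = freqs.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("zero total weight")
    return PositionalFrequencyMatrix(freqs / totals, n_sequences=n_seq,
                                     weighting=weighting)


def information_content(pfm: PositionalFrequencyMatrix,
                        background: Sequence[float] | None = None,
                        small_sample_correction: bool = False) -> LogoData:
    """Information content and letter heights from a frequency matrix.

    Stop frequencies are excluded and the amino-acid frequencies
    renormalized per position.  With the default uniform background,
    ``IC = log2(20) - H(p) - e(n)`` (e(n) only when the correction is on);
    with a non-uniform background IC is the relative entropy to it.
    All-stop positions are reported as NaN.
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (_N_AA,) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 20 probabilities summing to 1")
    uniform = np.allclose(bg, 1.0 / _N_AA)

    aa = pfm.freqs[:, :_N_AA]
    totals = aa.sum(axis=1)
    ic = np.full(pfm.length, np.nan)
    heights = np.full((pfm.length, _N_AA), np.nan)
    for pos in range(pfm.length):
        if totals[pos] <= 0:
            warnings.warn(f"position {pos + 1} contains only stop codons; undefined")
            continue
        p = aa[pos] / totals[pos]
        nz = p > 0
        if uniform:
            h = -np.sum(p[nz] * np.log2(p[nz]))
            val = math.log2(_N_AA) - h
            if small_sample_correction and pfm.n_sequences > 0:
                val -= (_N_AA - 1) / (2 * math.log(2) * pfm.n_sequences)
            val = max(val, 0.0)
        else:
            val = float(np.sum(p[nz] * np.log2(p[nz] / bg[nz])))
            val = max(val, 0.0)
        ic[pos] = val
        heights[pos] = p * val
    return LogoData(information=ic, heights=heights, height_sd=None, background=bg)


def bootstrap_sd(motifs: Sequence[str],
                 background: Sequence[float] | None = None,
                 B: int = 200,
                 seed: int = 0,
                 small_sample_correction: bool = False) -> np.ndarray:
    """Bootstrap standard deviation of letter heights, element-wise.

    Resamples the motif list with replacement ``B`` times (each replicate
    is treated as a multiset), recomputes heights, and reports per
    position/letter SDs.  Fully reproducible for a fixed seed.  With fewer
    than two distinct motifs every SD is 0 (with a warning).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    stripped = [m.replace("/", "") for m in motifs]
    length = _validate_motifs(stripped)
    if len(set(stripped)) < 2:
        warnings.warn("fewer than 2 distinct motifs; bootstrap SDs are 0")
        return np.zeros((length, _N_AA))
    rng = np.random.default_rng(seed)
    n = len(stripped)
    arr = np.array(stripped)
    samples = np.empty((B, length, _N_AA))
    for b in range(B):
        resample = arr[rng.integers(0, n, size=n)]
        counts: dict[str, int] = {}
        for m in resample:
            counts[m] = counts.get(m, 0) + 1
        pfm = frequency_matrix(list(counts), weights=list(counts.values()))
        # n_sequences for the correction should reflect the resample size
        pfm.n_sequences = n
        samples[b] = information_content(
            pfm, background, small_sample_correction).heights
    return np.nanstd(samples, axis=0, ddof=0)


def write_matrix_tsv(data: PositionalFrequencyMatrix | LogoData, path: str | Path) -> None:
    data.to_frame().to_csv(path, sep="\t")


def plot_logo(logo: LogoData, sd: np.ndarray | None = None, ax=None, title: str | None = None):
    """Render a stacked-letter information logo with optional SD error bars.

    Thin, replaceable matplotlib layer; no numeric output depends on it.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.6 * len(logo.information)), 3))
    cmap = plt.get_cmap("tab20")
    colors = {aa: cmap(i % 20) for i, aa in enumerate(AA_LETTERS)}
    for pos in range(len(logo.information)):
        if np.isnan(logo.information[pos]):
            continue
        order = np.argsort(logo.heights[pos])
        y = 0.0
        for j in order:
            h = logo.heights[pos, j]
            if h <= 0:
                continue
            aa = AA_LETTERS[j]
            ax.add_patch(Rectangle((pos + 0.05, y), 0.9, h,
                                   facecolor=colors[aa], edgecolor="none"))
            if h > 0.15:
                ax.text(pos + 0.5, y + h / 2, aa, ha="center", va="center",
                        fontsize=8, fontweight="bold")
            y += h
        if sd is not None:
            top_j = int(np.argmax(logo.heights[pos]))
            ax.errorbar(pos + 0.5, y, yerr=sd[pos, top_j], color="k",
                        capsize=2, lw=0.8)
    ax.set_xlim(0, len(logo.information))
    ax.set_ylim(0, math.log2(_N_AA) * 1.05)
    ax.set_xticks(np.arange(len(logo.information)) + 0.5,
                  [str(i + 1) for i in range(len(logo.information))])
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    return ax
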