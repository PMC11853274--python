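"""Positional hexamer counting and subset dispersion profiles.

For N aligned 100-base windows, a 6-base sliding window with 1-base step
gives 95 hexamer start sites, labelled -50..-1, +1..+45 (a hexamer is
indexed by its first base).  At each site the hexamer frequency
distribution over the 4096-word vocabulary is summarized, for every
dinucleotide subset, by the dispersion

    rho_XY = sigma_XY / sigma

the ratio of the population standard deviation of the member frequencies
(about the member mean) to that of the full vocabulary.  rho < 1 flags
conservative (narrow) usage of the subset at that site, rho > 1 random
usage.  The ratio is invariant to counts-vs-frequencies scaling and to the
n vs n-1 variance convention as long as numerator and denominator agree;
population (divide-by-n) form is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .kmers import PATTERNS, SubsetPartition
from .windows import WINDOW_LENGTH, AcceptorWindow, offset_to_label

K = 6
N_SITES = WINDOW_LENGTH - K + 1  # 95
VOCAB = 4**K


class DegenerateDistributionError(ValueError):
    """All hexamer frequencies equal at a site: rho is undefined."""


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Sequences (equal length) -> uint8 array of base codes A=0..T=3."""
    if not seqs:
        raise ValueError("no sequences supplied")
    length = len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = _ENCODE[raw].reshape(len(seqs), length)
    if (arr == 255).any():
        raise ValueError("sequences contain non-ACGT characters")
    return arr


@dataclass(frozen=True)
class PositionalKmerMatrix:
    """Hexamer occurrence counts per start site: shape (95, 4096)."""

    counts: np.ndarray
    n_sequences: int
    site_labels: Tuple[int, ...]
    k: int = K

    def __post_init__(self):
        if self.counts.shape != (len(self.site_labels), 4**self.k):
            raise ValueError("counts shape inconsistent with site labels and k")

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences


def kmer_site_labels(k: int = K) -> List[int]:
    """Start-site labels for k-mers in a 100-base window: -50..-1, +1..+(51-k)."""
    return [offset_to_label(o) for o in range(WINDOW_LENGTH - k + 1)]


def count_kmers_by_site(
    windows: Iterable[AcceptorWindow] | Sequence[str], k: int = K
) -> PositionalKmerMatrix:
    """Count the k-mer starting at every site across all windows.

    Accepts AcceptorWindow objects or plain 100-base strings.
    """
    seqs = [w.sequence if isinstance(w, AcceptorWindow) else w for w in windows]
    enc = encode_sequences(seqs)
    if enc.shape[1] != WINDOW_LENGTH:
        raise ValueError(f"windows must be {WINDOW_LENGTH} bases")
    n_sites = WINDOW_LENGTH - k + 1
    weights = 4 ** np.arange(k - 1, -1, -1)
    ranks = sliding_window_view(enc, k, axis=1).astype(np.int64) @ weights
    counts = np.zeros((n_sites, 4**k), dtype=np.int64)
    for s in range(n_sites):
        counts[s] = np.bincount(ranks[:, s], minlength=4**k)
    return PositionalKmerMatrix(
        counts=counts, n_sequences=len(seqs), site_labels=tuple(kmer_site_labels(k)), k=k
    )


def _as_mask(members, size: int) -> np.ndarray:
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("member set must be non-empty")
    if members.dtype == bool:
        if members.size != size:
            raise ValueError("boolean member mask has wrong length")
        mask = members
    else:
        mask = np.zeros(size, dtype=bool)
        mask[members] = True
    if not mask.any():
        raise ValueError("member set must be non-empty")
    return mask


def subset_sigma(values: Sequence[float], members) -> float:
    """Population standard deviation of the member values about the member mean."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("counts/frequencies must be non-negative")
    mask = _as_mask(members, values.size)
    return float(values[mask].std())


def dispersion_ratio(values: Sequence[float], members) -> float:
    """rho = sigma(member values) / sigma(all values).

    Scale-invariant: counts and frequencies give the same ratio.  Raises
    DegenerateDistributionError when the total distribution is constant.
    """
    values = np.asarray(values, dtype=float)
    sigma_total = float(values.std())
    if sigma_total == 0.0:
        raise DegenerateDistributionError("total frequency distribution is constant")
    return subset_sigma(values, members) / sigma_total


def profile(
    matrix: PositionalKmerMatrix, partition: SubsetPartition | None = None
) -> pd.DataFrame:
    """Dispersion of every XY1/XY0 subset at every site, as a tidy table.

    Columns: site, pattern, subset_class, rho, sigma_subset, sigma_total,
    n_sequences.  One row per site x 16 patterns x {XY1, XY0}.
    """
    if partition is None:
        partition = SubsetPartition.build(matrix.k)
    if partition.k != matrix.k:
        raise ValueError("partition k does not match matrix k")
    freqs = matrix.frequencies()
    rows = []
    for i, site in enumerate(matrix.site_labels):
        f = freqs[i]
        sigma_total = float(f.std())
        if sigma_total == 0.0:
            raise DegenerateDistributionError(f"constant hexamer distribution at site {site}")
        for pat in PATTERNS:
            mask = partition.membership[pat]
            for cls, m in (("XY1", mask), ("XY0", ~mask)):
                s = float(f[m].std())
                rows.append((site, pat, cls, s / sigma_total, s, sigma_total,
                             matrix.n_sequences))
    return pd.DataFrame(
        rows,
        columns=["site", "pattern", "subset_class", "rho", "sigma_subset",
                 "sigma_total", "n_sequences"],
    )


def profile_wide(profile_df: pd.DataFrame, subset_class: str = "XY1") -> pd.DataFrame:
    """Pattern x site matrix of rho values for one subset class."""
    sub = profile_df[profile_df["subset_class"] == subset_class]
    return sub.pivot(index="pattern", columns="site", values="rho")


def plot_profile(profile_df: pd.DataFrame, pattern: str, ax=None):
    """Line chart of the XY1 and XY0 dispersion curves for one pattern."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    for cls, color in (("XY1", "tab:blue"), ("XY0", "tab:red")):
        sub = profile_df[
            (profile_df["pattern"] == pattern) & (profile_df["subset_class"] == cls)
        ].sort_values("site")
        ax.plot(range(len(sub)), sub["rho"], label=f"{pattern}{'1' if cls == 'XY1' else '0'}",
                color=color)
    labels = sorted(profile_df["site"].unique())
    ticks = range(0, len(labels), 10)
    ax.set_xticks(list(ticks), [labels[t] for t in ticks])
    ax.axhline(1.0, lw=0.5, color="grey")
    ax.set_xlabel("site")
    ax.set_ylabel(r"$\rho$")
    ax.legend()
    return ax
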