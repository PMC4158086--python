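"""Position frequency matrices, information content, and positional nulls.

The observed stitched reads give a 100-column position frequency matrix
(PFM) whose per-column information content is ``2 + sum_b f_b log2 f_b``
bits (0 for a uniform column, 2 for a single-base column; no
small-sample correction).  The positional null resamples, per
chromosome, as many uniform positions (with replacement) as breaks were
observed there, assigns strands with the chromosome's observed
plus-strand proportion, and rebuilds a PFM per replicate — giving an
empirical envelope against which column-wise signal is judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .catalog import MASK, N_CONTEXT, N_READ, BreakCatalog, StitchedRead
from .genome import Genome, revcomp

N_COLUMNS = N_CONTEXT + N_READ
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PositionFrequencyMatrix:
    """Column-wise base frequencies over up-to-100-column stitched reads."""

    freqs: np.ndarray  # (100, 4), rows with n == 0 are all-zero
    n: np.ndarray  # (100,) reads contributing per column

    def __post_init__(self) -> None:
        if self.freqs.shape != (N_COLUMNS, 4) or self.n.shape != (N_COLUMNS,):
            raise ValueError("PFM must be 100 columns x 4 bases")


def build_pfm(stitched: Iterable[StitchedRead]) -> PositionFrequencyMatrix:
    """Count unmasked bases per column and normalize to frequencies."""
    counts = np.zeros((N_COLUMNS, 4), dtype=np.int64)
    any_read = False
    for sr in stitched:
        any_read = True
        for j, ch in enumerate(sr.columns):
            if ch != MASK:
                counts[j, _BASE_INDEX[ch]] += 1
    if not any_read:
        raise ValueError("cannot build a PFM from zero stitched reads")
    n = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    nz = n > 0
    freqs[nz] = counts[nz] / n[nz, None]
    return PositionFrequencyMatrix(freqs=freqs, n=n)


def _pfm_from_windows(windows: Sequence[str]) -> PositionFrequencyMatrix:
    counts = np.zeros((N_COLUMNS, 4), dtype=np.int64)
    for w in windows:
        for j, ch in enumerate(w):
            counts[j, _BASE_INDEX[ch]] += 1
    n = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    nz = n > 0
    freqs[nz] = counts[nz] / n[nz, None]
    return PositionFrequencyMatrix(freqs=freqs, n=n)


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-column IC in bits: ``2 + sum_b f log2 f`` with 0*log0 = 0.

    Columns with no contributing reads return NaN.
    """
    f = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic[pfm.n == 0] = np.nan
    return ic


def composition_ic(composition: Sequence[float]) -> float:
    """IC of the genome's own base composition (the null baseline)."""
    f = np.asarray(composition, dtype=float)
    f = f[f > 0]
    return float(2.0 + (f * np.log2(f)).sum())


@dataclass
class NullLogoSet:
    """PFM replicates from the positional null resampling."""

    pfms: list[PositionFrequencyMatrix]
    per_chromosome: dict[str, int]  # sampled positions per chromosome
    plus_proportions: dict[str, float]
    seed: int
    n_resampled: int  # edge draws that had to be redrawn

    def column_ic(self, column: int) -> np.ndarray:
        """IC of one (0-based) column across all replicates."""
        return np.array([information_content(p)[column] for p in self.pfms])

    def ic_matrix(self) -> np.ndarray:
        """(n_sim, 100) information content of every replicate."""
        return np.vstack([information_content(p) for p in self.pfms])


def simulate_null_logos(
    catalog: BreakCatalog,
    genome: Genome,
    n_sim: int = 100,
    seed: int = 0,
) -> NullLogoSet:
    """Positional null: uniform per-chromosome positions, observed strand mix.

    For each chromosome the number of sampled positions equals the
    observed break count there; strand is drawn with the observed
    plus-strand proportion.  Each sampled position is treated as a break
    call and a 100-base window extracted around it (the sampled base is
    the first read column, column 51); windows that would run off a
    chromosome end are redrawn (counted in ``n_resampled``).
    """
    if catalog.n_reads == 0:
        raise ValueError("catalog is empty")
    per_chrom = catalog.per_chromosome()
    plus_prop = catalog.plus_strand_proportion()
    rng = np.random.default_rng(seed)
    pfms = []
    n_resampled = 0
    for _ in range(n_sim):
        windows: list[str] = []
        for chrom, n_breaks in per_chrom.items():
            seq = genome[chrom]
            L = len(seq)
            p_plus = plus_prop.get(chrom, 0.5)
            drawn = 0
            while drawn < n_breaks:
                pos = int(rng.integers(0, L))
                strand = "+" if rng.random() < p_plus else "-"
                if strand == "+":
                    if pos - N_CONTEXT < 0 or pos + N_READ > L:
                        n_resampled += 1
                        continue
                    window = seq[pos - N_CONTEXT : pos + N_READ]
                else:
                    if pos - (N_READ - 1) < 0 or pos + 1 + N_CONTEXT > L:
                        n_resampled += 1
                        continue
                    window = revcomp(seq[pos - (N_READ - 1) : pos + 1 + N_CONTEXT])
                windows.append(window)
                drawn += 1
        pfms.append(_pfm_from_windows(windows))
    return NullLogoSet(
        pfms=pfms,
        per_chromosome=dict(per_chrom),
        plus_proportions=dict(plus_prop),
        seed=seed,
        n_resampled=n_resampled,
    )


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    ic = information_content(pfm)
    with open(path, "w") as fh:
        fh.write("column\tn\tfA\tfC\tfG\tfT\tIC\n")
        for j in range(N_COLUMNS):
            fA, fC, fG, fT = pfm.freqs[j]
            fh.write(
                f"{j + 1}\t{pfm.n[j]}\t{fA:.6g}\t{fC:.6g}\t{fG:.6g}\t{fT:.6g}\t"
                f"{ic[j]:.6g}\n"
            )


_LOGO_COLORS = {"A": "tab:green", "C": "tab:blue", "G": "tab:orange", "T": "tab:red"}


def plot_logo(
    pfm: PositionFrequencyMatrix,
    path: str | Path,
    scale: str = "ic",
) -> None:
    """Stacked-letter logo; column height = IC bits, or equal heights.

    A deliberately small matplotlib renderer (letters as scaled text):
    the statistics live in the PFM/IC functions, this is presentation.
    """
    if scale not in ("ic", "equal"):
        raise ValueError("scale must be 'ic' or 'equal'")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = information_content(pfm)
    fig, ax = plt.subplots(figsize=(14, 3))
    for j in range(N_COLUMNS):
        if pfm.n[j] == 0:
            continue
        height = ic[j] if scale == "ic" else 1.0
        y = 0.0
        order = np.argsort(pfm.freqs[j])  # small letters at the bottom
        for b in order:
            f = pfm.freqs[j, b]
            if f <= 0:
                continue
            h = f * height
            ax.text(
                j + 1, y + h / 2, BASES[b],
                ha="center", va="center",
                fontsize=7, color=_LOGO_COLORS[BASES[b]],
                stretch="condensed",
            )
            y += h
    ax.axvline(N_CONTEXT + 0.5, color="k", lw=0.8)
    ax.set_xlim(0, N_COLUMNS + 1)
    ax.set_ylim(0, 2.0 if scale == "ic" else 1.05)
    ax.set_xlabel("column (break between 50 and 51)")
    ax.set_ylabel("bits" if scale == "ic" else "frequency")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
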