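"""Optional thermodynamic folding backend (ViennaRNA adapter).

Implements the same :class:`~backfold.folding.PairProbMatrix` contract as
the built-in engine, but with the full nearest-neighbour thermodynamic
model of the ViennaRNA package: global folding via the RNAfold partition
function for short sequences, sliding-window (RNAplfold) probabilities for
long ones.  The window length doubles as the maximal pair span, and the
windowed averaging convention is RNAplfold's own.

The ``RNA`` python bindings ship with the ViennaRNA distribution and are
imported lazily; :func:`available` reports whether the backend can be used.
A small parser for RNAplfold's plain-text ``_basepairs`` output and the
PostScript dot-plot (``_dp.ps``) format is included so externally produced
probability files can be loaded into the same matrix type.
"""

from __future__ import annotations

import re

import numpy as np

from .folding import FoldParams, PairProbMatrix

__all__ = [
    "available",
    "ViennaRNAEngine",
    "matrix_from_plfold_basepairs",
    "matrix_from_dotplot_ps",
]


def _import_rna():
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on install
        raise ImportError(
            "the ViennaRNA python bindings (module 'RNA') are not installed; "
            "use the built-in engine instead"
        ) from exc
    return RNA


def available() -> bool:
    try:
        _import_rna()
    except ImportError:
        return False
    return True


class ViennaRNAEngine:
    """Folding engine backed by the ViennaRNA thermodynamic model.

    Only ``window`` and ``local_threshold`` of :class:`FoldParams` apply;
    the energy parameters are ViennaRNA's (Turner model).
    """

    name = "viennarna"

    def __init__(self, params: FoldParams | None = None):
        self.params = params or FoldParams()
        self._rna = _import_rna()

    def _md_window(self):
        md = self._rna.md()
        md.window_size = self.params.window
        md.max_bp_span = self.params.window
        return md

    def pair_probabilities(self, sequence: str) -> PairProbMatrix:
        rna_seq = sequence.upper().replace("T", "U")
        n = len(rna_seq)
        RNA = self._rna
        if n < self.params.local_threshold:
            fc = RNA.fold_compound(rna_seq)
            fc.pf()
            bpp = np.array(fc.bpp())  # (n+1, n+1), 1-based upper triangle
            band = np.zeros((n, max(n - 1, 1)))
            for d in range(1, n):
                idx = np.arange(1, n - d + 1)
                band[: n - d, d - 1] = bpp[idx, idx + d]
            return PairProbMatrix(band, windowed=False)

        fc = RNA.fold_compound(rna_seq, self._md_window(), RNA.OPTION_WINDOW)
        band = np.zeros((n, self.params.window))  # spans up to the window length

        window = self.params.window

        def callback(v, v_size, i, maxsize, what, data):
            if what & RNA.PROBS_WINDOW_BPP:
                # only spans up to the window can be nonzero; avoid walking
                # the full 1-based row of mostly-None entries
                hi = min(i + window, len(v) - 1)
                for j in range(i + 1, hi + 1):
                    p = v[j]
                    if p is not None and p > 0.0:
                        data[i - 1, j - i - 1] = p

        fc.probs_window(0, RNA.PROBS_WINDOW_BPP, callback, band)
        return PairProbMatrix(band, windowed=True)

    def dbf(self, sequence: str) -> float:
        m = self.pair_probabilities(sequence)
        return float(m.row_sums().mean())

    def dbf_many(self, sequences: list[str]) -> np.ndarray:
        return np.array([self.dbf(s) for s in sequences])


def matrix_from_plfold_basepairs(path, n: int, window: int) -> PairProbMatrix:
    """Load an RNAplfold ``_basepairs`` file (``i j p`` lines, 1-based)."""
    band = np.zeros((n, window))
    with open(path) as handle:
        for line in handle:
            parts = line.split()
            if len(parts) != 3:
                continue
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
            band[i - 1, j - i - 1] = p
    return PairProbMatrix(band, windowed=True)


_UBOX_RE = re.compile(r"^(\d+)\s+(\d+)\s+([\d.eE+-]+)\s+ubox\s*$")


def matrix_from_dotplot_ps(path, n: int) -> PairProbMatrix:
    """Load pair probabilities from an RNAfold/RNAplfold ``_dp.ps`` dot plot.

    ``ubox`` entries store the square root of the probability.
    """
    band = np.zeros((n, max(n - 1, 1)))
    with open(path) as handle:
        for line in handle:
            m = _UBOX_RE.match(line.strip())
            if m:
                i, j, sq = int(m.group(1)), int(m.group(2)), float(m.group(3))
                band[i - 1, j - i - 1] = sq * sq
    return PairProbMatrix(band, windowed=False)
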