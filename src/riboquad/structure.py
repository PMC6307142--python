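"""Quadruplex motif scanning, G4-aware folding energies, landscapes, periodicity.

The central quantity is the quadruplex stabilization energy

    dG0_rG4 = dG0_dsRNA - dG0_dsRNA+rG4

i.e. the minimum free energy of a sequence folded with only Watson-Crick
(and GU) pairing, minus the minimum free energy when quadruplex blocks are
additionally permitted.  Because allowing an extra structural option can
only stabilize, dG0_dsRNA+rG4 <= dG0_dsRNA and the difference is a
non-negative stabilization *gain*.  Figures conventionally plot the negated
(signed) view, where more negative means a more stable quadruplex; both
views are exposed (see :func:`g4_delta` and :func:`landscape`).

The default folding backend is an internal maximum-stability dynamic
program scoring helix stacks, with a parametric quadruplex block term
E(L, l) = a*(L-1) + b*ln(l-2) for L stacked quartets and total loop
length l.  A thermodynamic engine (e.g. RNAfold) can be plugged in through
the ``backend`` argument of :func:`fold_energy`.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import validate_rna

# ---------------------------------------------------------------------------
# Motif grammars
# ---------------------------------------------------------------------------

#: pattern_id -> (min G-tract length, min loop, max loop); four tracts, three loops
MOTIF_PATTERNS: dict[str, tuple[int, int, int]] = {
    "G3N7": (3, 1, 7),
    "G2N1": (2, 1, 1),
    "G2N3": (2, 1, 3),
    "G2N5": (2, 1, 5),
}


@dataclass(frozen=True)
class MotifMatch:
    pattern_id: str
    start: int  # 0-based
    end: int  # half-open
    n_tracts: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


def _grammar_regex(min_tract: int, loop_min: int, loop_max: int) -> re.Pattern:
    return re.compile(
        "G{%d,}(?:[ACGU]{%d,%d}G{%d,}){3}" % (min_tract, loop_min, loop_max, min_tract)
    )


def g_runs(sequence: str, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= ``min_len`` as (start, end) half-open."""
    return [
        (m.start(), m.end())
        for m in re.finditer("G{%d,}" % min_len, sequence)
    ]


def scan_motifs(sequence: str, pattern_id: str = "G3N7") -> list[MotifMatch]:
    """All substrings of ``sequence`` matching a four-G-tract grammar.

    Every (start, end) whose substring can be parsed as four G-tracts of at
    least the pattern's minimum length separated by three loops within the
    pattern's loop-length range is reported; overlapping and nested matches
    are all kept (tracts may exceed the minimum length, and a match may
    begin inside a longer G-run).
    """
    validate_rna(sequence)
    min_tract, loop_min, loop_max = MOTIF_PATTERNS[pattern_id]
    rx = _grammar_regex(min_tract, loop_min, loop_max)
    g_pos = [i for i, c in enumerate(sequence) if c == "G"]
    min_len = 4 * min_tract + 3 * loop_min
    max_len = 4 * len(sequence) + 3 * loop_max  # no tract-length cap
    matches = []
    for i in g_pos:
        for j in g_pos:
            length = j + 1 - i
            if length < min_len or length > max_len:
                continue
            if rx.fullmatch(sequence, i, j + 1):
                n_tracts = sum(
                    1 for s, e in g_runs(sequence[i : j + 1], min_tract)
                )
                matches.append(MotifMatch(pattern_id, i, j + 1, n_tracts))
    return matches


# ---------------------------------------------------------------------------
# Folding model
# ---------------------------------------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class FoldParams:
    """Parameters of the internal folding model.

    stack_energy
        kcal/mol contributed by each stacked base pair (a helix of h pairs
        scores (h-1)*stack_energy); isolated pairs score nothing.
    min_hairpin
        Minimum unpaired nucleotides closed by a pair.
    g4_a, g4_b
        Quadruplex block energy E = g4_a*(L-1) + g4_b*ln(l-2), with L the
        number of stacked quartets (min tract length, capped at
        g4_max_quartets) and l the total loop length.
    g4_min_tract, g4_loop_min, g4_loop_max
        Grammar of the quadruplex blocks admitted by the energy model.
    """

    stack_energy: float = -2.0
    min_hairpin: int = 3
    g4_a: float = -18.0
    g4_b: float = 12.0
    g4_min_tract: int = 3
    g4_loop_min: int = 1
    g4_loop_max: int = 7
    g4_max_quartets: int = 4


DEFAULT_FOLD_PARAMS = FoldParams()


def g4_blocks(sequence: str, params: FoldParams = DEFAULT_FOLD_PARAMS):
    """Candidate quadruplex blocks as (start, end, energy) triples.

    Blocks are built from 4-tuples of maximal G-runs whose inter-run gaps
    respect the loop-length range; only stabilizing (negative-energy)
    blocks are returned.
    """
    runs = g_runs(sequence, params.g4_min_tract)
    out = []
    n = len(runs)
    for a in range(n - 3):
        s0, e0 = runs[a]
        for b in range(a + 1, n - 2):
            l1 = runs[b][0] - e0
            if l1 > params.g4_loop_max:
                break
            if l1 < params.g4_loop_min:
                continue
            for c in range(b + 1, n - 1):
                l2 = runs[c][0] - runs[b][1]
                if l2 > params.g4_loop_max:
                    break
                if l2 < params.g4_loop_min:
                    continue
                for d in range(c + 1, n):
                    l3 = runs[d][0] - runs[c][1]
                    if l3 > params.g4_loop_max:
                        break
                    if l3 < params.g4_loop_min:
                        continue
                    tracts = (e0 - s0, runs[b][1] - runs[b][0],
                              runs[c][1] - runs[c][0], runs[d][1] - runs[d][0])
                    quartets = min(min(tracts), params.g4_max_quartets)
                    loops = l1 + l2 + l3
                    energy = params.g4_a * (quartets - 1) + params.g4_b * math.log(loops - 2)
                    if energy < 0:
                        out.append((s0, runs[d][1], energy))
    return out


@njit(cache=True)
def _fold_dp(pair, bstart, bend, benergy, stack, min_hairpin):  # pragma: no cover
    n = pair.shape[0]
    if n == 0:
        return 0.0
    W = np.zeros((n, n))
    V = np.full((n, n), np.inf)
    nb = bstart.shape[0]
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # V: energy given (i, j) paired
            if pair[i, j] and j - i - 1 >= min_hairpin:
                v = W[i + 1, j - 1] if i + 1 <= j - 1 else 0.0
                if (
                    pair[i + 1, j - 1]
                    and (j - 1) - (i + 1) - 1 >= min_hairpin
                    and V[i + 1, j - 1] + stack < v
                ):
                    v = V[i + 1, j - 1] + stack
                V[i, j] = v
            # W: best energy on [i, j]
            best = W[i + 1, j] if i + 1 <= j else 0.0
            for k in range(i + min_hairpin + 1, j + 1):
                if pair[i, k] and V[i, k] < np.inf:
                    rest = W[k + 1, j] if k + 1 <= j else 0.0
                    if V[i, k] + rest < best:
                        best = V[i, k] + rest
            for bi in range(nb):
                if bstart[bi] == i and bend[bi] - 1 <= j:
                    rest = W[bend[bi], j] if bend[bi] <= j else 0.0
                    if benergy[bi] + rest < best:
                        best = benergy[bi] + rest
            if best > 0.0:
                best = 0.0
            W[i, j] = best
    return W[0, n - 1]


def _pair_matrix(sequence: str) -> np.ndarray:
    n = len(sequence)
    mat = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(i + 1, n):
            if (sequence[i], sequence[j]) in _PAIRS:
                mat[i, j] = True
    return mat


def fold_energy(
    sequence: str,
    allow_g4: bool = False,
    params: FoldParams = DEFAULT_FOLD_PARAMS,
    backend=None,
) -> float:
    """Minimum free energy (kcal/mol, <= 0) of ``sequence``.

    With ``allow_g4`` the parametric quadruplex block term is additionally
    permitted in the recursion.  ``backend``, if given, is a callable
    ``backend(sequence, allow_g4) -> float`` replacing the internal model
    (e.g. a thermodynamic folding engine).
    """
    validate_rna(sequence)
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    if backend is not None:
        return float(backend(sequence, allow_g4))
    if allow_g4:
        blocks = g4_blocks(sequence, params)
    else:
        blocks = []
    if blocks:
        bstart = np.array([b[0] for b in blocks], dtype=np.int64)
        bend = np.array([b[1] for b in blocks], dtype=np.int64)
        benergy = np.array([b[2] for b in blocks], dtype=np.float64)
    else:
        bstart = np.empty(0, dtype=np.int64)
        bend = np.empty(0, dtype=np.int64)
        benergy = np.empty(0, dtype=np.float64)
    return float(
        _fold_dp(
            _pair_matrix(sequence), bstart, bend, benergy,
            float(params.stack_energy), int(params.min_hairpin),
        )
    )


@dataclass
class EnergyTriple:
    """Paired folding energies of one sequence (kcal/mol).

    ``dg_g4 = dg_ds - dg_ds_g4`` is the stabilization gained by allowing
    quadruplex formation (>= 0); the *signed* view used in plots is its
    negation.  ``zscore`` is attached by :func:`g4_delta_cohort`.
    """

    dg_ds: float
    dg_ds_g4: float
    dg_g4: float
    length: int
    dg_ds_per_nt: float = field(init=False)
    dg_g4_per_nt: float = field(init=False)
    zscore: float | None = None

    def __post_init__(self) -> None:
        self.dg_ds_per_nt = self.dg_ds / self.length
        self.dg_g4_per_nt = self.dg_g4 / self.length

    @property
    def dg_g4_signed(self) -> float:
        return -self.dg_g4


def g4_delta(
    sequence: str, params: FoldParams = DEFAULT_FOLD_PARAMS, backend=None
) -> EnergyTriple:
    """Fold ``sequence`` with and without quadruplexes; report the difference."""
    dg_ds = fold_energy(sequence, allow_g4=False, params=params, backend=backend)
    dg_ds_g4 = fold_energy(sequence, allow_g4=True, params=params, backend=backend)
    return EnergyTriple(dg_ds, dg_ds_g4, dg_ds - dg_ds_g4, len(sequence))


def g4_delta_cohort(
    sequences: dict[str, str],
    params: FoldParams = DEFAULT_FOLD_PARAMS,
    backend=None,
):
    """Per-sequence :func:`g4_delta` with cohort z-scores of the
    length-normalized stabilization.

    A zero-variance cohort gets z = 0 everywhere (with a warning).
    Returns ``{name: EnergyTriple}``.
    """
    triples = {
        name: g4_delta(seq, params=params, backend=backend)
        for name, seq in sequences.items()
    }
    vals = np.array([t.dg_g4_per_nt for t in triples.values()])
    sd = vals.std(ddof=0)
    if sd == 0:
        warnings.warn("zero-variance cohort; all z-scores set to 0")
        z = np.zeros_like(vals)
    else:
        z = (vals - vals.mean()) / sd
    for t, zi in zip(triples.values(), z):
        t.zscore = float(zi)
    return triples


# ---------------------------------------------------------------------------
# Landscapes and periodicity
# ---------------------------------------------------------------------------

LANDSCAPE_VIEWS = ("g4_signed", "g4_gain", "ds")


@dataclass
class Landscape:
    """Sliding-window energy track with smoothed local minima.

    ``positions[t]`` is the transcript coordinate of the *center* of the
    t-th window; ``minima`` are offsets of strict local minima of the
    smoothed track, relative to the anchor.
    """

    positions: np.ndarray
    window_energy: np.ndarray
    smoothed_positions: np.ndarray
    smoothed: np.ndarray
    minima: list[int]
    anchor: int
    window: int
    smooth: int
    view: str


def _plateau_minima(values: np.ndarray) -> list[int]:
    """Indices of strict local minima; plateaus report their left edge."""
    out = []
    m = len(values)
    i = 1
    while i < m - 1:
        j = i
        while j + 1 < m and values[j + 1] == values[i]:
            j += 1
        if j < m - 1 and values[i] < values[i - 1] and values[i] < values[j + 1]:
            out.append(i)
        i = j + 1
    return out


def landscape(
    sequence: str,
    anchor: int = 0,
    window: int = 35,
    smooth: int = 10,
    view: str = "g4_signed",
    params: FoldParams = DEFAULT_FOLD_PARAMS,
    backend=None,
) -> Landscape:
    """Positional folding-energy landscape over a sequence.

    Position i of the raw track holds the energy of sequence[i, i+window);
    the smoothed track is a running mean over ``smooth`` consecutive
    windows.  With the default view ("g4_signed", the negated quadruplex
    stabilization) stable quadruplexes appear as local minima near the
    motif center.
    """
    if view not in LANDSCAPE_VIEWS:
        raise ValueError(f"view must be one of {LANDSCAPE_VIEWS}")
    validate_rna(sequence)
    n = len(sequence)
    if n < window:
        warnings.warn(f"sequence length {n} < window {window}; empty landscape")
        empty = np.empty(0)
        return Landscape(empty, empty, empty, empty, [], anchor, window, smooth, view)
    vals = np.empty(n - window + 1)
    for i in range(n - window + 1):
        sub = sequence[i : i + window]
        if view == "ds":
            vals[i] = fold_energy(sub, allow_g4=False, params=params, backend=backend)
        else:
            t = g4_delta(sub, params=params, backend=backend)
            vals[i] = t.dg_g4_signed if view == "g4_signed" else t.dg_g4
    positions = np.arange(n - window + 1) + window // 2
    if len(vals) >= smooth:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(vals, kernel, mode="valid")
        sm_pos = np.arange(len(sm)) + window // 2 + smooth // 2
    else:
        sm = vals.copy()
        sm_pos = positions.copy()
    minima = [int(sm_pos[i]) - anchor for i in _plateau_minima(sm)]
    return Landscape(positions, vals, sm_pos, sm, minima, anchor, window, smooth, view)


@dataclass
class Periodogram:
    frequency: np.ndarray  # cycles per nucleotide
    power: np.ndarray
    dominant_period: float  # nt


def periodicity(
    offsets,
    max_offset: int,
    taper: bool = False,
) -> Periodogram:
    """Fourier periodogram of pooled positional offsets.

    Offsets (e.g. quadruplex landscape minima relative to uORF start
    codons, pooled across uORFs) are binned into a per-nucleotide count
    signal on [0, max_offset), mean-detrended, and transformed with an
    unpadded discrete Fourier transform.  The dominant period is 1/f at
    maximal power over f > 0.  With ``taper`` a 10% cosine (Tukey) taper
    is applied after detrending.
    """
    offsets = np.asarray(list(offsets), dtype=np.int64)
    if len(offsets) < 10:
        raise ValueError(
            "need at least 10 offsets; pool minima across uORFs before "
            "calling periodicity"
        )
    offsets = offsets[(offsets >= 0) & (offsets < max_offset)]
    signal = np.bincount(offsets, minlength=max_offset).astype(float)
    signal = signal - signal.mean()
    if taper:
        from scipy.signal.windows import tukey

        signal = signal * tukey(len(signal), alpha=0.1)
    spectrum = np.fft.rfft(signal)
    power = np.abs(spectrum) ** 2
    freq = np.fft.rfftfreq(len(signal), d=1.0)
    k = 1 + int(np.argmax(power[1:]))
    return Periodogram(freq, power, float(1.0 / freq[k]))


def ribosome_span(diameter_angstrom: float, per_nt_angstrom: float = 6.5) -> int:
    """Nucleotides covered by a ribosome of a given diameter.

    A human 80S ribosome of 250-300 A diameter at 6.5 A per nucleotide of
    the ribosome/mRNA complex covers floor(diameter / per_nt) = 38-46 nt.
    """
    if diameter_angstrom <= 0 or per_nt_angstrom <= 0:
        raise ValueError("diameter and per-nt spacing must be positive")
    return int(diameter_angstrom // per_nt_angstrom)
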