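"""RNA secondary-structure prediction and shuffle-based significance testing.

Two folding modes are provided:

``maxpair``
    Nussinov-style dynamic program maximizing the number of nested canonical
    base pairs (AU, GC, GU) subject to a minimum hairpin-loop size. This is
    the substrate for the structural criteria used in miRNA discovery.

``energy``
    A reduced nearest-neighbor model (Zuker-style recursion over stack free
    energies, loop-length penalties and a linear multiloop cost). Scores are
    in kcal/mol with the open chain as the zero reference; more negative is
    more stable. The parameter table ships with the package as editable TSV
    (:data:`DEFAULT_PARAMS_PATH`) and approximates, rather than reproduces,
    a full thermodynamic folder.

Significance of a fold is assessed RANDfold-style: the observed score is
compared against folds of dinucleotide-preserving (Altschul-Erickson)
shuffles of the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._seq import to_rna

try:  # pragma: no cover - numba is a hard dependency, guarded defensively
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "FoldResult",
    "HairpinAnatomy",
    "ShuffleTest",
    "EnergyParams",
    "fold_maxpair",
    "fold_energy",
    "parse_hairpin",
    "shuffle_pvalue",
    "dinucleotide_shuffle",
    "load_energy_params",
]

DEFAULT_PARAMS_PATH = resources.files("mirforge") / "data" / "energy_params.tsv"

_BASES = "ACGU"
_IDX = {b: i for i, b in enumerate(_BASES)}
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_PAIR_OK = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in _CANONICAL:
    _PAIR_OK[_IDX[_a], _IDX[_b]] = True

_INF = 1e9
_MAX_INTERNAL = 30  # cap on total unpaired bases in an internal loop/bulge


# ---------------------------------------------------------------------------
# containers


@dataclass
class FoldResult:
    """A nested secondary structure for ``seq`` (RNA alphabet)."""

    seq: str
    dotbracket: str
    pairs: frozenset  # frozenset of (i, j) tuples, i < j, 0-based
    score: float
    mode: str  # "maxpair" | "energy"

    def partner(self) -> dict:
        """Map each paired index to its partner."""
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class HairpinAnatomy:
    stem_pairs: int
    loop_span: tuple | None  # (start, end) 0-based half-open, unpaired loop
    arm5: tuple | None
    arm3: tuple | None
    n_hairpin_loops: int
    has_bifurcation: bool
    unstructured: bool = False


@dataclass
class ShuffleTest:
    n_shuffles: int
    observed: float
    null_scores: list = field(repr=False, default_factory=list)
    p_value: float = 1.0
    mode: str = "maxpair"


# ---------------------------------------------------------------------------
# encoding helpers


def _encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    try:
        return np.array([_IDX[c] for c in rna], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid character in sequence: {exc.args[0]!r}") from None


def _dotbracket(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# maxpair (Nussinov) fold


@njit(cache=False)
def _nussinov_fill(x, pair_ok, min_loop):  # pragma: no cover - numba kernel
    n = x.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pair_ok[x[i], x[k]]:
                    v = 1
                    if k - 1 >= i + 1:
                        v += m[i + 1, k - 1]
                    if k + 1 <= j:
                        v += m[k + 1, j]
                    if v > best:
                        best = v
            m[i, j] = best
    return m


def _nussinov_traceback(m: np.ndarray, x: np.ndarray, min_loop: int) -> set:
    """Deterministic traceback: when pairing base i is optimal, pair it with
    the smallest qualifying partner; otherwise leave i unpaired."""
    n = x.shape[0]
    pairs = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop or m[i, j] == 0:
            continue
        target = m[i, j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _PAIR_OK[x[i], x[k]]:
                v = 1
                v += m[i + 1, k - 1] if k - 1 >= i + 1 else 0
                v += m[k + 1, j] if k + 1 <= j else 0
                if v == target:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def fold_maxpair(seq: str, min_loop: int = 3) -> FoldResult:
    """Maximum-cardinality nested canonical pairing of ``seq``.

    Parameters
    ----------
    seq
        Nucleotide sequence (DNA or RNA alphabet; normalized to RNA).
    min_loop
        Minimum number of unpaired bases closed by any pair (steric
        hairpin-loop constraint).
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    x = _encode(seq)
    n = len(x)
    if n <= min_loop + 1:
        return FoldResult(to_rna(seq), "." * n, frozenset(), 0.0, "maxpair")
    m = _nussinov_fill(x, _PAIR_OK, min_loop)
    pairs = _nussinov_traceback(m, x, min_loop)
    return FoldResult(
        seq=to_rna(seq),
        dotbracket=_dotbracket(n, pairs),
        pairs=frozenset(pairs),
        score=float(m[0, n - 1]),
        mode="maxpair",
    )


# ---------------------------------------------------------------------------
# energy parameters


@dataclass
class EnergyParams:
    """Nearest-neighbor parameter set for the reduced energy model."""

    stack: dict  # ("XY","ZW") -> kcal/mol
    hairpin: dict  # loop length -> kcal/mol
    internal: dict  # unpaired total -> kcal/mol
    ml_closing: float
    ml_branch: float
    ml_unpaired: float
    extrapolate_coef: float

    def hairpin_penalty(self, length: int) -> float:
        mx = max(self.hairpin)
        if length in self.hairpin:
            return self.hairpin[length]
        if length < min(self.hairpin):
            return _INF
        return self.hairpin[mx] + self.extrapolate_coef * math.log(length / mx)

    def internal_penalty(self, size: int) -> float:
        mx = max(self.internal)
        if size in self.internal:
            return self.internal[size]
        return self.internal[mx] + self.extrapolate_coef * math.log(size / mx)

    def stack_table(self) -> np.ndarray:
        t = np.full((4, 4, 4, 4), _INF)
        for (outer, inner), dg in self.stack.items():
            t[_IDX[outer[0]], _IDX[outer[1]], _IDX[inner[0]], _IDX[inner[1]]] = dg
        return t


def load_energy_params(path: str | Path | None = None) -> EnergyParams:
    """Load the TSV parameter table, validating completeness."""
    text = (
        Path(path).read_text() if path is not None else DEFAULT_PARAMS_PATH.read_text()
    )
    stack, hairpin, internal, ml = {}, {}, {}, {}
    coef = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            outer, inner = key.split(",")
            stack[(outer, inner)] = float(value)
        elif kind == "hairpin":
            hairpin[int(key)] = float(value)
        elif kind == "internal":
            internal[int(key)] = float(value)
        elif kind == "multiloop":
            ml[key] = float(value)
        elif kind == "extrapolate":
            coef = float(value)
        else:
            raise ValueError(f"unknown parameter row kind {kind!r}")
    for outer, inner in ((o, i) for o in map("".join, _CANONICAL) for i in map("".join, _CANONICAL)):
        if (outer, inner) not in stack:
            raise KeyError(f"missing stack entry {outer},{inner}")
    if not hairpin or not internal:
        raise KeyError("missing loop penalty rows")
    for k in ("closing", "branch", "unpaired"):
        if k not in ml:
            raise KeyError(f"missing multiloop entry {k!r}")
    if coef is None:
        raise KeyError("missing extrapolate coefficient")
    return EnergyParams(
        stack=stack,
        hairpin=hairpin,
        internal=internal,
        ml_closing=ml["closing"],
        ml_branch=ml["branch"],
        ml_unpaired=ml["unpaired"],
        extrapolate_coef=coef,
    )


_DEFAULT_PARAMS: EnergyParams | None = None


def _default_params() -> EnergyParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_energy_params()
    return _DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# energy fold (reduced Zuker recursion)


@njit(cache=False)
def _zuker_fill(x, pair_ok, stack, hairpin_p, internal_p, ml_a, ml_b, ml_c, min_loop, max_int):  # pragma: no cover
    n = x.shape[0]
    v = np.full((n, n), _INF)
    wm = np.full((n, n), _INF)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if pair_ok[x[i], x[j]]:
                best = hairpin_p[j - i - 1]
                # stacks / internal loops / bulges
                for k in range(i + 1, j - min_loop - 1):
                    n1 = k - i - 1
                    if n1 > max_int:
                        break
                    for l in range(j - 1, k + min_loop, -1):
                        n2 = j - l - 1
                        if n1 + n2 > max_int:
                            break
                        if pair_ok[x[k], x[l]] and v[k, l] < _INF:
                            if n1 == 0 and n2 == 0:
                                e = v[k, l] + stack[x[i], x[j], x[k], x[l]]
                            else:
                                e = v[k, l] + internal_p[n1 + n2]
                            if e < best:
                                best = e
                # multiloop (>=2 branches inside)
                for mmid in range(i + 2, j - 2):
                    if wm[i + 1, mmid] < _INF and wm[mmid + 1, j - 1] < _INF:
                        e = ml_a + wm[i + 1, mmid] + wm[mmid + 1, j - 1]
                        if e < best:
                            best = e
                v[i, j] = best
            # WM: segment inside a multiloop with >= 1 branch
            best = _INF
            if wm[i + 1, j] < _INF and i + 1 <= j:
                best = wm[i + 1, j] + ml_c
            if j - 1 >= i and wm[i, j - 1] < _INF:
                e = wm[i, j - 1] + ml_c
                if e < best:
                    best = e
            if v[i, j] < _INF:
                e = v[i, j] + ml_b
                if e < best:
                    best = e
            for mmid in range(i + 1, j):
                if wm[i, mmid] < _INF and wm[mmid + 1, j] < _INF:
                    e = wm[i, mmid] + wm[mmid + 1, j]
                    if e < best:
                        best = e
            wm[i, j] = best
    # external loop
    w = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = w[j - 1]
        for i in range(j - 1):
            if v[i, j - 1] < _INF:
                e = w[i] + v[i, j - 1]
                if e < best:
                    best = e
        w[j] = best
    return v, wm, w


_TOL = 1e-6


def _trace_energy(x, v, wm, w, p: EnergyParams, stack4, min_loop):
    """Python traceback mirroring the DP decision structure."""
    n = x.shape[0]
    hair = {l: p.hairpin_penalty(l) for l in range(0, n + 1)}
    intp = {s: p.internal_penalty(s) for s in range(1, n + 1)}
    pairs = set()
    tasks = [("W", 0, n)]
    while tasks:
        kind, a, b = tasks.pop()
        if kind == "W":
            j = b
            while j > 0:
                if abs(w[j] - w[j - 1]) < _TOL:
                    j -= 1
                    continue
                hit = False
                for i in range(j - 1):
                    if v[i, j - 1] < _INF and abs(w[j] - (w[i] + v[i, j - 1])) < _TOL:
                        tasks.append(("V", i, j - 1))
                        j = i
                        hit = True
                        break
                if not hit:
                    j -= 1
        elif kind == "V":
            i, j = a, b
            pairs.add((i, j))
            target = v[i, j]
            if j - i - 1 >= min_loop and abs(target - hair[j - i - 1]) < _TOL:
                continue
            found = False
            for k in range(i + 1, j - min_loop - 1):
                n1 = k - i - 1
                if n1 > _MAX_INTERNAL or found:
                    break
                for l in range(j - 1, k + min_loop, -1):
                    n2 = j - l - 1
                    if n1 + n2 > _MAX_INTERNAL:
                        break
                    if _PAIR_OK[x[k], x[l]] and v[k, l] < _INF:
                        e = v[k, l] + (
                            stack4[x[i], x[j], x[k], x[l]]
                            if n1 == 0 and n2 == 0
                            else intp[n1 + n2]
                        )
                        if abs(target - e) < _TOL:
                            tasks.append(("V", k, l))
                            found = True
                            break
            if found:
                continue
            for mmid in range(i + 2, j - 2):
                if wm[i + 1, mmid] < _INF and wm[mmid + 1, j - 1] < _INF:
                    e = p.ml_closing + wm[i + 1, mmid] + wm[mmid + 1, j - 1]
                    if abs(target - e) < _TOL:
                        tasks.append(("M", i + 1, mmid))
                        tasks.append(("M", mmid + 1, j - 1))
                        found = True
                        break
        else:  # WM segment
            i, j = a, b
            target = wm[i, j]
            if target >= _INF:
                continue
            if v[i, j] < _INF and abs(target - (v[i, j] + p.ml_branch)) < _TOL:
                tasks.append(("V", i, j))
            elif i + 1 <= j and wm[i + 1, j] < _INF and abs(target - (wm[i + 1, j] + p.ml_unpaired)) < _TOL:
                tasks.append(("M", i + 1, j))
            elif j - 1 >= i and wm[i, j - 1] < _INF and abs(target - (wm[i, j - 1] + p.ml_unpaired)) < _TOL:
                tasks.append(("M", i, j - 1))
            else:
                for mmid in range(i + 1, j):
                    if wm[i, mmid] < _INF and wm[mmid + 1, j] < _INF:
                        if abs(target - (wm[i, mmid] + wm[mmid + 1, j])) < _TOL:
                            tasks.append(("M", i, mmid))
                            tasks.append(("M", mmid + 1, j))
                            break
    return pairs


def fold_energy(
    seq: str, params: EnergyParams | None = None, min_loop: int = 3
) -> FoldResult:
    """Minimum-free-energy nested structure under the reduced model.

    Returns score 0.0 (open chain) for sequences that cannot form any
    stabilizing structure.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    p = params if params is not None else _default_params()
    x = _encode(seq)
    n = len(x)
    if n <= min_loop + 1:
        return FoldResult(to_rna(seq), "." * n, frozenset(), 0.0, "energy")
    hair = np.array([p.hairpin_penalty(l) for l in range(n + 1)])
    intp = np.full(n + 1, _INF)
    for s in range(1, n + 1):
        intp[s] = p.internal_penalty(s)
    stack4 = p.stack_table()
    v, wm, w = _zuker_fill(
        x, _PAIR_OK, stack4, hair, intp,
        p.ml_closing, p.ml_branch, p.ml_unpaired, min_loop, _MAX_INTERNAL,
    )
    score = float(min(w[n], 0.0))
    pairs = _trace_energy(x, v, wm, w, p, stack4, min_loop) if score < 0 else set()
    return FoldResult(
        seq=to_rna(seq),
        dotbracket=_dotbracket(n, pairs),
        pairs=frozenset(pairs),
        score=round(score, 6),
        mode="energy",
    )


# ---------------------------------------------------------------------------
# hairpin anatomy


def parse_hairpin(fold: FoldResult, span: tuple | None = None) -> HairpinAnatomy:
    """Count hairpin loops closed inside ``span`` and locate the stem arms.

    A hairpin loop is a pair enclosing no other pair. ``span`` is a 0-based
    half-open interval on the sequence (defaults to the full sequence).
    """
    n = len(fold.seq)
    if span is None:
        span = (0, n)
    lo, hi = span
    if hi <= lo:
        raise ValueError("empty span")
    inside = sorted((i, j) for i, j in fold.pairs if lo <= i and j < hi)
    # hairpin-closing pairs: innermost pairs (no pair nested within)
    closing = []
    for i, j in inside:
        if not any(i < a and b < j for a, b in inside):
            closing.append((i, j))
    n_loops = len(closing)
    if n_loops == 0:
        return HairpinAnatomy(
            stem_pairs=len(inside), loop_span=None, arm5=None, arm3=None,
            n_hairpin_loops=0, has_bifurcation=False, unstructured=True,
        )
    if n_loops == 1:
        ci, cj = closing[0]
        return HairpinAnatomy(
            stem_pairs=len(inside),
            loop_span=(ci + 1, cj),
            arm5=(lo, ci + 1),
            arm3=(cj, hi),
            n_hairpin_loops=1,
            has_bifurcation=False,
        )
    return HairpinAnatomy(
        stem_pairs=len(inside), loop_span=None, arm5=None, arm3=None,
        n_hairpin_loops=n_loops, has_bifurcation=True,
    )


# ---------------------------------------------------------------------------
# dinucleotide shuffle + significance


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving the exact dinucleotide counts.

    Builds the dinucleotide multigraph, draws a random last-edge arborescence
    toward the terminal vertex, randomizes the remaining edge orderings, and
    walks the Eulerian path.
    """
    s = to_rna(seq)
    if len(s) < 3 or len(set(s)) == 1:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = sorted(edges)
    while True:
        last_edge = {}
        for vtx in vertices:
            if vtx == last:
                continue
            last_edge[vtx] = edges[vtx][rng.integers(len(edges[vtx]))]
        # every non-terminal vertex must reach `last` via designated edges
        ok = True
        for vtx in last_edge:
            seen = set()
            cur = vtx
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    ordered: dict[str, list[str]] = {}
    for vtx in vertices:
        pool = list(edges[vtx])
        if vtx in last_edge:
            pool.remove(last_edge[vtx])
        rng.shuffle(pool)
        if vtx in last_edge:
            pool.append(last_edge[vtx])
        ordered[vtx] = pool
    out = [s[0]]
    cursor = {vtx: 0 for vtx in vertices}
    cur = s[0]
    total = len(s) - 1
    for _ in range(total):
        nxt = ordered[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_pvalue(
    seq: str,
    n_shuffles: int = 99,
    mode: str = "maxpair",
    rng_seed: int = 0,
    params: EnergyParams | None = None,
) -> ShuffleTest:
    """Empirical fold-stability P-value against dinucleotide-preserving nulls.

    p = (1 + #{null at least as stable as observed}) / (n_shuffles + 1).
    In energy mode "at least as stable" means null free energy <= observed;
    in maxpair mode it means null pair count >= observed.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3")
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19 to resolve p <= 0.05")
    if mode not in ("maxpair", "energy"):
        raise ValueError(f"unknown fold mode {mode!r}")

    def _score(s: str) -> float:
        if mode == "maxpair":
            return fold_maxpair(s).score
        return fold_energy(s, params=params).score

    observed = _score(seq)
    rng = np.random.default_rng(rng_seed)
    nulls = []
    extreme = 0
    for _ in range(n_shuffles):
        ns = _score(dinucleotide_shuffle(seq, rng))
        nulls.append(ns)
        if (mode == "energy" and ns <= observed) or (
            mode == "maxpair" and ns >= observed
        ):
            extreme += 1
    return ShuffleTest(
        n_shuffles=n_shuffles,
        observed=observed,
        null_scores=nulls,
        p_value=(1 + extreme) / (n_shuffles + 1),
        mode=mode,
    )
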