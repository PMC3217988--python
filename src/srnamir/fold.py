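"""RNA secondary-structure folding engines.

The discovery stage needs, for each candidate precursor window, a single
lowest-energy structure in dot-bracket notation plus its folding free
energy.  Two interchangeable engines are provided:

``vienna``
    Thermodynamic minimum-free-energy folding through the ViennaRNA
    Python bindings (kcal/mol).  Used by default when importable.

``surrogate``
    A self-contained base-pair-maximization folder (Nussinov recursion,
    minimum hairpin loop 3 nt) with a simple pairing-energy surrogate:
    -2 per G:C pair, -1 per A:U or G:U pair.  Its "energies" rank
    structures but are not thermodynamic free energies and must never be
    compared numerically against published kcal/mol values.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import RNA as _vienna_rna
except ImportError:  # pragma: no cover
    _vienna_rna = None

_VALID = set("ACGU")
_PAIR_ENERGY = {
    ("G", "C"): -2.0, ("C", "G"): -2.0,
    ("A", "U"): -1.0, ("U", "A"): -1.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
MIN_LOOP = 3


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _check(seq: str) -> str:
    rna = to_rna(seq)
    bad = set(rna) - _VALID
    if bad:
        raise ValueError(f"non-ACGU symbols in sequence: {sorted(bad)}")
    return rna


def fold_vienna(seq: str) -> tuple[str, float]:
    """Lowest-energy structure and MFE (kcal/mol) from ViennaRNA."""
    if _vienna_rna is None:
        raise RuntimeError("ViennaRNA python bindings are not available")
    structure, mfe = _vienna_rna.fold(_check(seq))
    return structure, float(mfe)


def fold_surrogate(seq: str) -> tuple[str, float]:
    """Base-pair-maximizing structure with surrogate pairing energies.

    Nussinov-style dynamic program minimizing summed pair energies
    (equivalently maximizing weighted pairs), minimum loop 3 nt.
    Deterministic: ties resolve toward the unpaired branch, then the
    smallest bifurcation point.
    """
    rna = _check(seq)
    n = len(rna)
    if n == 0:
        return "", 0.0
    codes = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in rna])
    etab = np.zeros((4, 4))
    for (a, b), e in _PAIR_ENERGY.items():
        etab[{"A": 0, "C": 1, "G": 2, "U": 3}[a],
             {"A": 0, "C": 1, "G": 2, "U": 3}[b]] = e
    pair_e = etab[codes[:, None], codes[None, :]]  # energy of pairing i with j
    pairable = pair_e < 0

    # E[i][j]: best (lowest) energy of rna[i..j] inclusive; 0 for short spans
    E = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        i_arr = np.arange(0, n - span)
        j_arr = i_arr + span
        # option 1: j unpaired
        best = E[i_arr, j_arr - 1].copy()
        # option 2: k pairs j, for k in [i, j - MIN_LOOP - 1]
        for off in range(0, span - MIN_LOOP):
            k_arr = i_arr + off
            e_kj = pair_e[k_arr, j_arr]
            left = np.where(k_arr > i_arr, E[i_arr, np.maximum(k_arr - 1, 0)], 0.0)
            inner = E[k_arr + 1, j_arr - 1]
            cand = left + inner + e_kj
            ok = pairable[k_arr, j_arr]
            best = np.where(ok & (cand < best), cand, best)
        E[i_arr, j_arr] = best

    partner: list[Optional[int]] = [None] * n

    def traceback(i: int, j: int) -> None:
        while j > i:
            if j - i < MIN_LOOP + 1 or E[i, j] == E[i, j - 1]:
                j -= 1
                continue
            for k in range(i, j - MIN_LOOP):
                if not pairable[k, j]:
                    continue
                left = E[i, k - 1] if k > i else 0.0
                inner = E[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                if np.isclose(left + inner + pair_e[k, j], E[i, j]):
                    partner[k], partner[j] = j, k
                    if k > i:
                        traceback(i, k - 1)
                    i, j = k + 1, j - 1
                    break
            else:  # pragma: no cover - defensive
                j -= 1

    traceback(0, n - 1)
    structure = "".join("(" if partner[i] is not None and partner[i] > i
                        else ")" if partner[i] is not None else "."
                        for i in range(n))
    return structure, float(E[0, n - 1])


_ENGINES = {"vienna": fold_vienna, "surrogate": fold_surrogate}


def default_engine() -> str:
    return "vienna" if _vienna_rna is not None else "surrogate"


def fold_mfe(seq: str, engine: str = "auto") -> tuple[str, float]:
    """Fold a sequence to its single lowest-energy structure.

    Parameters
    ----------
    seq
        Nucleotide sequence (DNA or RNA alphabet; T is read as U).
    engine
        "vienna", "surrogate", or "auto" (vienna when available).
    """
    if len(seq) < 1:
        raise ValueError("cannot fold an empty sequence")
    if engine == "auto":
        engine = default_engine()
    try:
        fold = _ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown folding engine {engine!r}") from None
    return fold(seq)


def pair_table(structure: str) -> list[Optional[int]]:
    """0-based partner index per position from a dot-bracket string."""
    stack: list[int] = []
    partner: list[Optional[int]] = [None] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partner


def structure_from_pairs(n: int, pairs: list[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        a, b = min(i, j), max(i, j)
        out[a], out[b] = "(", ")"
    return "".join(out)
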