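"""Temperature-dependent RNA minimum-free-energy folding.

A deliberately minimal Zuker-style dynamic program over a self-contained
nearest-neighbor model: Watson-Crick stack enthalpies/entropies from the
standard published set (Xia et al. 1998 values), simple tabulated loop
penalties (linear interpolation inside the table, logarithmic extrapolation
beyond it), a linear multibranch-loop term, minimum hairpin loop of 3, and
optional wobble (G.U) pairs — off by default, matching a --noGU analysis.

Because stacks have dH < 0 and dS < 0, every structure's free energy
dG(T) = dH - T*dS rises with temperature, so the MFE does too: folds are
more stable at 20 C than at 35 C, which is the comparative question the
module answers.  Dangling ends, coaxial stacking and special hairpins are
not modeled; absolute kcal/mol values are therefore not comparable with
full-parameter folders, while distribution shifts across temperature are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .editing_caller import EditingSite
from .seqio import revcomp

INF = 1e9
MAX_LOOP = 30  # max bulge/internal loop size considered (standard cutoff)
R_EXTRAPOLATE = 1.08  # kcal/mol, ~1.75*R*T310 for Jacobson-Stockmayer growth

_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC_PAIRS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")]
_GU_PAIRS = [("G", "U"), ("U", "G")]

# 5'-b1 b2-3' / 3'-b1' b2'-5' stacks keyed by ((b1, b1'), (b2, b2')).
# dH in kcal/mol, dS in cal/(mol*K); the 10 unique Watson-Crick stacks, the
# remaining 6 filled by the symmetry E[(a,b),(c,d)] = E[(d,c),(b,a)].
_WC_STACKS: dict[tuple[tuple[str, str], tuple[str, str]], tuple[float, float]] = {
    (("A", "U"), ("A", "U")): (-6.82, -19.0),
    (("A", "U"), ("U", "A")): (-9.38, -26.7),
    (("U", "A"), ("A", "U")): (-7.69, -20.5),
    (("C", "G"), ("U", "A")): (-10.48, -27.1),
    (("C", "G"), ("A", "U")): (-10.44, -26.9),
    (("G", "C"), ("U", "A")): (-11.40, -29.5),
    (("G", "C"), ("A", "U")): (-12.44, -32.5),
    (("C", "G"), ("G", "C")): (-10.64, -26.7),
    (("G", "C"), ("G", "C")): (-13.39, -32.7),
    (("G", "C"), ("C", "G")): (-14.88, -36.9),
}


def _complete_wc_stacks() -> dict:
    full = dict(_WC_STACKS)
    for bp1 in _WC_PAIRS:
        for bp2 in _WC_PAIRS:
            if (bp1, bp2) in full:
                continue
            mirror = ((bp2[1], bp2[0]), (bp1[1], bp1[0]))
            full[(bp1, bp2)] = full[mirror]
    return full


@dataclass
class EnergyModel:
    """Nearest-neighbor parameters; all stacks must have dH < 0 and dS < 0
    and loop penalties must be >= 0 and non-decreasing in length."""

    #: {(inner 5' pair, outer 3' pair): (dH, dS)}
    stack_dh: dict = field(default_factory=_complete_wc_stacks)
    #: hairpin-loop initiation dG (kcal/mol) for sizes 3..9
    hairpin_table: tuple = (5.4, 5.6, 5.7, 5.8, 6.0, 6.1, 6.4)
    #: bulge-loop dG for sizes 1..6
    bulge_table: tuple = (3.8, 3.9, 4.0, 4.2, 4.4, 4.5)
    #: internal-loop dG for total sizes 2..8
    internal_table: tuple = (1.5, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8)
    multiloop_closing: float = 3.4  # a: per multiloop
    multiloop_branch: float = 0.4  # b: per branch (incl. closing pair)
    multiloop_unpaired: float = 0.0  # c: per unpaired base
    min_hairpin: int = 3
    allow_gu: bool = False
    #: coarse uniform wobble-stack parameters used only when allow_gu is set
    gu_stack_dh_ds: tuple = (-8.0, -23.0)
    gu_gu_stack_dh_ds: tuple = (-6.0, -18.0)

    def __post_init__(self) -> None:
        for (dh, ds) in self.stack_dh.values():
            if dh >= 0 or ds >= 0:
                raise ValueError("stack parameters must have dH < 0 and dS < 0")
        for table in (self.hairpin_table, self.bulge_table, self.internal_table):
            if any(x < 0 for x in table):
                raise ValueError("loop penalties must be >= 0")
            if any(b < a for a, b in zip(table, table[1:])):
                raise ValueError("loop penalties must be non-decreasing in length")

    # -- derived numeric tables --------------------------------------------

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return _WC_PAIRS + (_GU_PAIRS if self.allow_gu else [])

    def pair_type_matrix(self) -> np.ndarray:
        pt = np.full((4, 4), -1, dtype=np.int8)
        for k, (a, b) in enumerate(self.pairs):
            pt[_BASE_TO_IDX[a], _BASE_TO_IDX[b]] = k
        return pt

    def stack_energy_matrix(self, celsius: float) -> np.ndarray:
        """dG(T) = dH - T*dS/1000 for every (inner pair, outer pair) stack."""
        t_kelvin = celsius + 273.15
        npairs = len(self.pairs)
        e = np.full((npairs, npairs), INF)
        for i, bp1 in enumerate(self.pairs):
            for j, bp2 in enumerate(self.pairs):
                if (bp1, bp2) in self.stack_dh:
                    dh, ds = self.stack_dh[(bp1, bp2)]
                elif self.allow_gu:
                    both_gu = bp1 in _GU_PAIRS and bp2 in _GU_PAIRS
                    dh, ds = self.gu_gu_stack_dh_ds if both_gu else self.gu_stack_dh_ds
                else:  # pragma: no cover - unreachable without GU
                    continue
                e[i, j] = dh - t_kelvin * ds / 1000.0
        return e

    def _loop_array(self, table: tuple, first_size: int, max_size: int) -> np.ndarray:
        out = np.full(max_size + 1, INF)
        for k, g in enumerate(table):
            n = first_size + k
            if n <= max_size:
                out[n] = g
        n_last = first_size + len(table) - 1
        for n in range(n_last + 1, max_size + 1):
            out[n] = table[-1] + R_EXTRAPOLATE * math.log(n / n_last)
        return out

    def hairpin_energies(self, max_size: int) -> np.ndarray:
        arr = self._loop_array(self.hairpin_table, 3, max(max_size, 3))
        arr[: self.min_hairpin] = INF
        return arr

    def bulge_energies(self) -> np.ndarray:
        return self._loop_array(self.bulge_table, 1, MAX_LOOP)

    def internal_energies(self) -> np.ndarray:
        return self._loop_array(self.internal_table, 2, MAX_LOOP)


@dataclass
class FoldResult:
    sequence: str  # RNA alphabet
    temperature: float  # Celsius
    mfe: float  # kcal/mol
    structure: str  # dot-bracket
    pairs: dict[int, int] = field(default_factory=dict)


def encode_rna(seq: str) -> np.ndarray:
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters for folding: {sorted(bad)}")
    return np.array([_BASE_TO_IDX[b] for b in rna], dtype=np.int8)


# ---------------------------------------------------------------------------
# DP fill (numba-compiled when available)
# ---------------------------------------------------------------------------


def _fill_dp(seq, pt, stack_e, hairpin_e, bulge_e, internal_e, a_ml, b_ml, c_ml, min_hp):
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    W = np.zeros(n + 1)
    for span in range(min_hp + 1, n):
        for i in range(0, n - span):
            j = i + span
            p_ij = pt[seq[i], seq[j]]
            if p_ij >= 0:
                best = hairpin_e[j - i - 1]
                # stacks, bulges and internal loops closing (i, j)
                for k in range(i + 1, j - min_hp - 1):
                    n1 = k - i - 1
                    if n1 > MAX_LOOP:
                        break
                    for l in range(j - 1, k + min_hp, -1):
                        n2 = j - l - 1
                        if n1 + n2 > MAX_LOOP:
                            break
                        p_kl = pt[seq[k], seq[l]]
                        if p_kl < 0 or V[k, l] >= INF:
                            continue
                        if n1 == 0 and n2 == 0:
                            e = stack_e[p_ij, p_kl] + V[k, l]
                        elif n1 == 0 or n2 == 0:
                            e = bulge_e[n1 + n2] + V[k, l]
                        else:
                            e = internal_e[n1 + n2] + V[k, l]
                        if e < best:
                            best = e
                # multibranch loop closed by (i, j)
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = a_ml + b_ml + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: at least one branch inside [i, j]
            best = INF
            if V[i, j] < INF:
                best = V[i, j] + b_ml
            if WM[i + 1, j] + c_ml < best:
                best = WM[i + 1, j] + c_ml
            if WM[i, j - 1] + c_ml < best:
                best = WM[i, j - 1] + c_ml
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    if e < best:
                        best = e
            WM[i, j] = best
    for j in range(n):
        best = W[j]
        for i in range(0, j):
            if V[i, j] < INF:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        if V[0, j] < INF and V[0, j] < best:
            best = V[0, j]
        W[j + 1] = best
    return V, WM, W


_fill_dp_py = _fill_dp
try:  # compiled path: ~100x faster on 201-nt windows
    from numba import njit

    _fill_dp = njit(cache=True)(_fill_dp)
except Exception:  # pragma: no cover - numba present in supported envs
    pass


# ---------------------------------------------------------------------------
# Traceback
# ---------------------------------------------------------------------------


_EPS = 1e-9


def _traceback(seq, pt, stack_e, hairpin_e, bulge_e, internal_e, a_ml, b_ml, c_ml,
               min_hp, V, WM, W):
    n = len(seq)
    pairs: dict[int, int] = {}
    stack: list[tuple] = [("W", 0, n - 1)]
    while stack:
        tag, i, j = stack.pop()
        if j < i:
            continue
        if tag == "W":
            # prefer unpaired at the 3' end, then the 5'-most closing pair
            if abs(W[j + 1] - W[j]) < _EPS:
                stack.append(("W", i, j - 1))
                continue
            found = False
            for i0 in range(0, j):
                if V[i0, j] < INF and abs(W[i0] + V[i0, j] - W[j + 1]) < _EPS:
                    stack.append(("W", 0, i0 - 1))
                    stack.append(("V", i0, j))
                    found = True
                    break
            if not found and V[0, j] < INF and abs(V[0, j] - W[j + 1]) < _EPS:
                stack.append(("V", 0, j))
        elif tag == "V":
            pairs[i] = j
            pairs[j] = i
            target = V[i, j]
            if abs(hairpin_e[j - i - 1] - target) < _EPS:
                continue
            done = False
            for k in range(i + 1, j - min_hp - 1):
                n1 = k - i - 1
                if n1 > MAX_LOOP or done:
                    break
                for l in range(j - 1, k + min_hp, -1):
                    n2 = j - l - 1
                    if n1 + n2 > MAX_LOOP:
                        break
                    p_kl = pt[seq[k], seq[l]]
                    if p_kl < 0 or V[k, l] >= INF:
                        continue
                    if n1 == 0 and n2 == 0:
                        e = stack_e[pt[seq[i], seq[j]], p_kl] + V[k, l]
                    elif n1 == 0 or n2 == 0:
                        e = bulge_e[n1 + n2] + V[k, l]
                    else:
                        e = internal_e[n1 + n2] + V[k, l]
                    if abs(e - target) < _EPS:
                        stack.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if (
                    WM[i + 1, k] < INF
                    and WM[k + 1, j - 1] < INF
                    and abs(a_ml + b_ml + WM[i + 1, k] + WM[k + 1, j - 1] - target) < _EPS
                ):
                    stack.append(("M", i + 1, k))
                    stack.append(("M", k + 1, j - 1))
                    break
        else:  # WM
            target = WM[i, j]
            if target >= INF:
                continue
            if WM[i + 1, j] < INF and abs(WM[i + 1, j] + c_ml - target) < _EPS:
                stack.append(("M", i + 1, j))
            elif WM[i, j - 1] < INF and abs(WM[i, j - 1] + c_ml - target) < _EPS:
                stack.append(("M", i, j - 1))
            elif V[i, j] < INF and abs(V[i, j] + b_ml - target) < _EPS:
                stack.append(("V", i, j))
            else:
                for k in range(i, j):
                    if (
                        WM[i, k] < INF
                        and WM[k + 1, j] < INF
                        and abs(WM[i, k] + WM[k + 1, j] - target) < _EPS
                    ):
                        stack.append(("M", i, k))
                        stack.append(("M", k + 1, j))
                        break
    return {i: j for i, j in pairs.items() if i < j}


def fold_mfe(seq: str, celsius: float = 30.0, model: EnergyModel | None = None) -> FoldResult:
    """Minimum-free-energy fold of ``seq`` (DNA or RNA letters) at ``celsius``.

    Deterministic traceback: unpaired is preferred, then the 5'-most pairing.
    The empty structure (0 kcal/mol) is always admissible, so mfe <= 0.
    """
    model = model or EnergyModel()
    s = encode_rna(seq)
    rna = seq.upper().replace("T", "U")
    n = len(s)
    if n < model.min_hairpin + 2:
        return FoldResult(rna, celsius, 0.0, "." * n)
    pt = model.pair_type_matrix()
    stack_e = model.stack_energy_matrix(celsius)
    hairpin_e = model.hairpin_energies(n)
    bulge_e = model.bulge_energies()
    internal_e = model.internal_energies()
    args = (
        s,
        pt,
        stack_e,
        hairpin_e,
        bulge_e,
        internal_e,
        model.multiloop_closing,
        model.multiloop_branch,
        model.multiloop_unpaired,
        model.min_hairpin,
    )
    V, WM, W = _fill_dp(*args)
    mfe = min(0.0, float(W[n]))
    if mfe >= 0.0:
        return FoldResult(rna, celsius, 0.0, "." * n)
    pairs = _traceback(*args, V, WM, W)
    structure = ["."] * n
    for i, j in pairs.items():
        structure[i], structure[j] = "(", ")"
    return FoldResult(rna, celsius, mfe, "".join(structure), pairs=pairs)


# ---------------------------------------------------------------------------
# Energy of a given structure (loop decomposition) — shared with the tests'
# exhaustive-enumeration oracle and the traceback round-trip check.
# ---------------------------------------------------------------------------


def pairs_from_dotbracket(structure: str) -> dict[int, int]:
    stack, pairs = [], {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            pairs[stack.pop()] = i
    if stack:
        raise ValueError("unbalanced structure")
    return pairs


def structure_energy(
    seq: str, pairs: Mapping[int, int], celsius: float, model: EnergyModel | None = None
) -> float:
    """Free energy of an explicit structure under the same nearest-neighbor
    model as the DP (hairpin/stack/bulge/internal/multibranch decomposition;
    the exterior loop is free)."""
    model = model or EnergyModel()
    s = encode_rna(seq)
    pt = model.pair_type_matrix()
    stack_e = model.stack_energy_matrix(celsius)
    hairpin_e = model.hairpin_energies(len(s))
    bulge_e = model.bulge_energies()
    internal_e = model.internal_energies()
    pairmap: dict[int, int] = {}
    for i, j in pairs.items():
        a, b = (i, j) if i < j else (j, i)
        pairmap[a], pairmap[b] = b, a
    total = 0.0
    for i in sorted(k for k, v in pairmap.items() if k < v):
        j = pairmap[i]
        if pt[s[i], s[j]] < 0:
            raise ValueError(f"illegal pair ({i},{j}) under the model")
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in pairmap:
                children.append((k, pairmap[k]))
                k = pairmap[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            size = j - i - 1
            if size < model.min_hairpin:
                raise ValueError("hairpin loop below minimum size")
            total += hairpin_e[size]
        elif len(children) == 1:
            (k, l) = children[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += stack_e[pt[s[i], s[j]], pt[s[k], s[l]]]
            elif n1 == 0 or n2 == 0:
                total += bulge_e[n1 + n2]
            else:
                total += internal_e[n1 + n2]
        else:
            total += (
                model.multiloop_closing
                + model.multiloop_branch * (1 + len(children))
                + model.multiloop_unpaired * unpaired
            )
    return total


# ---------------------------------------------------------------------------
# Window extraction and distribution comparison
# ---------------------------------------------------------------------------


def extract_window(
    site: EditingSite, genome: Mapping[str, str], flank: int = 100
) -> tuple[str, bool]:
    """201-nt transcript-strand window centered on the edited A (as RNA).

    Near a contig edge the window is truncated rather than padded; the second
    return value flags truncation.
    """
    chrom = genome[site.chrom]
    lo, hi = max(0, site.pos - flank), min(len(chrom), site.pos + flank + 1)
    window = chrom[lo:hi]
    truncated = (hi - lo) != 2 * flank + 1
    if site.strand == "-":
        window = revcomp(window)
    return window.replace("T", "U"), truncated


def fold_windows(
    sites: Sequence[EditingSite],
    genome: Mapping[str, str],
    temperatures: Sequence[float] = (20.0, 30.0, 35.0),
    flank: int = 100,
    model: EnergyModel | None = None,
) -> list[dict]:
    """Fold the window around every site at every temperature."""
    model = model or EnergyModel()
    rows = []
    for site in sites:
        window, truncated = extract_window(site, genome, flank)
        for t in temperatures:
            res = fold_mfe(window, t, model)
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "strand": site.strand,
                    "temperature": t,
                    "mfe": res.mfe,
                    "structure": res.structure,
                    "truncated": truncated,
                }
            )
    return rows


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when min(n, m) <= 8 and tie-free,
    tie-corrected normal approximation otherwise."""
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("empty group")
    tie_free = len(set(x) | set(y)) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def compare_mfe_distributions(
    mfe_by_group: Mapping[str, Sequence[float]]
) -> dict[tuple[str, str], dict[str, float]]:
    """Pairwise Mann-Whitney comparisons of MFE distributions."""
    from itertools import combinations

    labels = list(mfe_by_group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for a, b in combinations(labels, 2):
        u, p = mann_whitney(mfe_by_group[a], mfe_by_group[b])
        out[(a, b)] = {"U": u, "p": p, "n_a": len(mfe_by_group[a]), "n_b": len(mfe_by_group[b])}
    return out
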