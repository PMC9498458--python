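"""Substitution-saturation diagnostics.

Two views of saturation in a multiple alignment:

* transition/transversion proportions of each taxon pair plotted against a
  corrected (TN93) pairwise distance, per codon-position stratum — in a
  saturated alignment the transversion curve overtakes the transition
  curve as distance grows;
* an entropy-based index of substitution saturation (Iss): the mean
  per-site Shannon entropy divided by the entropy expected at full
  saturation.  The full-saturation expectation is computed exactly for the
  alignment's number of sequences n as the mean plug-in entropy of an
  n-draw multinomial sample from the alignment's base frequencies, so an
  alignment of independently random sequences scores Iss ~ 1 at any n,
  while an invariant alignment scores 0.

Simulation-calibrated critical values for Iss (the significance verdict of
Xia's test) are not computed; Iss is reported as a descriptive index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .codes import is_transition
from .genomes import Alignment

__all__ = [
    "SaturationPoint",
    "IssResult",
    "InsufficientDataError",
    "ts_tv_curve",
    "iss",
    "tn93_distance",
    "k2p_distance",
]

_BASES = "ACGT"
MIN_COMPARABLE_SITES = 10


class InsufficientDataError(ValueError):
    pass


def _stratum_slice(seq: str, stratum) -> str:
    if stratum in ("all", "123", None):
        return seq
    p = int(stratum)
    if p not in (1, 2, 3):
        raise ValueError(f"stratum must be 1, 2, 3 or 'all', got {stratum!r}")
    return seq[p - 1::3]


def _pair_counts(s1: str, s2: str):
    """Comparable sites, transition/transversion/AG/CT difference counts and
    pooled base counts of a sequence pair (gap/N sites excluded pairwise)."""
    n = ts = tv = ag = ct = 0
    base_counts = {b: 0 for b in _BASES}
    for b1, b2 in zip(s1, s2):
        if b1 not in _BASES or b2 not in _BASES:
            continue
        n += 1
        base_counts[b1] += 1
        base_counts[b2] += 1
        if b1 != b2:
            if is_transition(b1, b2):
                ts += 1
                if {b1, b2} == {"A", "G"}:
                    ag += 1
                else:
                    ct += 1
            else:
                tv += 1
    return n, ts, tv, ag, ct, base_counts


def tn93_distance(s1: str, s2: str) -> float:
    """Tamura–Nei (1993) corrected distance; NaN when the correction is undefined."""
    n, _, tv, ag, ct, bc = _pair_counts(s1, s2)
    if n == 0:
        return math.nan
    total = sum(bc.values())
    fA, fC, fG, fT = (bc[b] / total for b in "ACGT")
    gR, gY = fA + fG, fC + fT
    P1, P2, Q = ag / n, ct / n, tv / n
    if fA * fG == 0 or fC * fT == 0 or gR * gY == 0:
        # degenerate frequencies: fall back to K2P behaviour
        return k2p_distance(s1, s2)
    k1 = 2 * fA * fG / gR
    k2 = 2 * fC * fT / gY
    k3 = 2 * (gR * gY - fA * fG * gY / gR - fC * fT * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def k2p_distance(s1: str, s2: str) -> float:
    """Kimura two-parameter corrected distance; NaN when undefined."""
    n, ts, tv, _, _, _ = _pair_counts(s1, s2)
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class SaturationPoint:
    taxon1: str
    taxon2: str
    stratum: str
    n_sites: int
    p_transition: float
    p_transversion: float
    distance: float


def ts_tv_curve(aln: Alignment, stratum="all") -> pd.DataFrame:
    """Transition/transversion proportions vs TN93 distance for all taxon pairs.

    Pairs with fewer than 10 comparable sites are excluded with a warning.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 sequences")
    rows: list[SaturationPoint] = []
    for (t1, s1), (t2, s2) in combinations(aln.rows, 2):
        x1, x2 = _stratum_slice(s1, stratum), _stratum_slice(s2, stratum)
        n, ts, tv, _, _, _ = _pair_counts(x1, x2)
        if n < MIN_COMPARABLE_SITES:
            warnings.warn(f"pair ({t1}, {t2}): only {n} comparable sites; excluded")
            continue
        rows.append(
            SaturationPoint(t1, t2, str(stratum), n, ts / n, tv / n, tn93_distance(x1, x2))
        )
    return pd.DataFrame(
        [(p.taxon1, p.taxon2, p.stratum, p.n_sites, p.p_transition,
          p.p_transversion, p.distance) for p in rows],
        columns=["taxon1", "taxon2", "stratum", "n_sites",
                 "p_transition", "p_transversion", "distance"],
    )


@dataclass(frozen=True)
class IssResult:
    stratum: str
    mean_entropy: float
    saturated_entropy: float
    iss: float
    n_sequences: int
    n_sites: int


def _expected_saturated_entropy(n: int, freqs: np.ndarray) -> float:
    """Exact E[plug-in entropy] of an n-draw multinomial sample from ``freqs``.

    Enumerates all compositions (n1..n4) of n; entropy in nats.
    """
    logf = np.log(np.where(freqs > 0, freqs, 1.0))
    lgam = math.lgamma
    expected = 0.0
    for n1 in range(n + 1):
        for n2 in range(n - n1 + 1):
            for n3 in range(n - n1 - n2 + 1):
                n4 = n - n1 - n2 - n3
                ns = (n1, n2, n3, n4)
                if any(c > 0 and freqs[i] == 0 for i, c in enumerate(ns)):
                    continue
                logp = lgam(n + 1) - sum(lgam(c + 1) for c in ns)
                logp += sum(c * logf[i] for i, c in enumerate(ns) if c)
                h = -sum((c / n) * math.log(c / n) for c in ns if c)
                expected += math.exp(logp) * h
    return expected


def iss(aln: Alignment, stratum="all") -> IssResult:
    """Entropy-based index of substitution saturation for one stratum.

    Requires >= 4 sequences and >= 50 sites in the stratum.  Sites where
    fewer than 2 bases are determined are skipped.
    """
    if aln.n_rows < 4:
        raise ValueError("Iss requires at least 4 sequences")
    strata = [_stratum_slice(s, stratum) for _, s in aln.rows]
    n_sites = len(strata[0])
    if n_sites < 50:
        raise InsufficientDataError(
            f"stratum {stratum!r} has {n_sites} sites; at least 50 required"
        )
    n = aln.n_rows
    base_totals = {b: 0 for b in _BASES}
    entropies = []
    for i in range(n_sites):
        col = [s[i] for s in strata if s[i] in _BASES]
        if len(col) < 2:
            continue
        counts = {b: col.count(b) for b in set(col)}
        m = len(col)
        entropies.append(-sum((c / m) * math.log(c / m) for c in counts.values()))
        for b, c in counts.items():
            base_totals[b] += c
    if not entropies:
        raise InsufficientDataError("no determinable sites in stratum")
    total = sum(base_totals.values())
    freqs = np.array([base_totals[b] / total for b in _BASES])
    h_sat = _expected_saturated_entropy(n, freqs)
    mean_h = float(np.mean(entropies))
    return IssResult(
        stratum=str(stratum),
        mean_entropy=mean_h,
        saturated_entropy=h_sat,
        iss=mean_h / h_sat if h_sat > 0 else math.nan,
        n_sequences=n,
        n_sites=len(entropies),
    )
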