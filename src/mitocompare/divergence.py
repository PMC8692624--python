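"""Pairwise and multi-sequence divergence statistics.

Implements, per gene alignment:

* nucleotide diversity (Pi): the mean pairwise proportion of differing
  sites, with pairwise deletion of gap/ambiguous sites;
* sliding-window Pi profiles (default 500 bp windows every 100 bp);
* Kimura 2-parameter distances, correcting separately for transitions (P)
  and transversions (Q):  d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q);
* Nei-Gojobori (1986) Ka/Ks: potential synonymous/nonsynonymous site counts
  with fractional sites, minimal-pathway averaging of observed differences
  (pathways through stop codons excluded), and Jukes-Cantor correction
  d = -3/4 ln(1 - 4p/3).

All site filtering is pairwise deletion: a site is dropped for a pair only
when either member carries a non-ACGT symbol there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional

import numpy as np

from .codon_usage import GeneticCode, vertebrate_mito_code

logger = logging.getLogger("mitocompare")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
NUCS = "ACGT"


class SaturationError(ValueError):
    """Distance undefined because the correction's log argument is <= 0."""


@dataclass
class GeneAlignment:
    """A gapless-or-gapped alignment of one gene across >= 2 taxa."""

    name: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"{self.name}: alignment needs >= 2 taxa")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.name}: unequal sequence lengths {lengths}")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)


@dataclass
class DiversityProfile:
    gene: str
    window: int
    step: int
    # (start, end, midpoint, pi); 1-based inclusive alignment coordinates
    windows: list[tuple[int, int, float, float]]
    overall_pi: float
    last_window_partial: bool


@dataclass
class DistanceResult:
    valid_sites: int
    p_distance: float
    transition_p: float        # P
    transversion_q: float      # Q
    d_k2p: float               # NaN when saturated
    saturated: bool


@dataclass
class KaKsResult:
    """Nei-Gojobori site and difference counts with corrected rates."""

    syn_sites: float           # S, averaged over the two sequences
    nonsyn_sites: float        # N
    syn_diffs: float           # Sd, pathway-averaged
    nonsyn_diffs: float        # Nd
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float               # Ka/Ks; 0 when Ka == 0; NaN + flag otherwise
    ratio_defined: bool
    codons_compared: int
    saturated: bool = False


# ---------------------------------------------------------------------------
# site-level machinery
# ---------------------------------------------------------------------------

def pairwise_differences(a: str, b: str) -> tuple[int, int, int]:
    """(valid sites, transitions, transversions) under pairwise deletion.

    Transitions are A<->G and C<->T; any site where either sequence carries
    a non-ACGT symbol (gap, N, IUPAC code) is excluded.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    aa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)       # A/G -> 1, C/T -> 2, else 0
    lut[[ord("A"), ord("G")]] = 1
    lut[[ord("C"), ord("T")]] = 2
    ca, cb = lut[aa], lut[bb]
    valid = (ca > 0) & (cb > 0)
    if not valid.any():
        raise ValueError("zero valid (unambiguous) sites")
    diff = valid & (aa != bb)
    ts = int((diff & (ca == cb)).sum())
    tv = int((diff & (ca != cb)).sum())
    return int(valid.sum()), ts, tv


def nucleotide_diversity(aln: GeneAlignment) -> float:
    """Pi: mean over unordered pairs of (differences / valid sites)."""
    vals = []
    for ta, tb in combinations(aln.taxa, 2):
        try:
            valid, ts, tv = pairwise_differences(aln.sequences[ta],
                                                 aln.sequences[tb])
        except ValueError:
            logger.warning("%s: pair (%s, %s) has no valid sites; skipped",
                           aln.name, ta, tb)
            continue
        vals.append((ts + tv) / valid)
    if not vals:
        raise ValueError(f"{aln.name}: no pair with valid sites")
    return float(np.mean(vals))


def sliding_window_pi(aln: GeneAlignment, window: int = 500,
                      step: int = 100) -> DiversityProfile:
    """Pi in sliding windows of ``window`` bp advancing by ``step`` bp.

    A final partial window (shorter than ``window``) is retained and
    flagged.  Alignments shorter than one window yield a single truncated
    window.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    length = aln.length
    rows: list[tuple[int, int, float, float]] = []
    partial = False
    start = 0
    while True:
        end = min(start + window, length)
        sub = GeneAlignment(aln.name, {t: s[start:end]
                                       for t, s in aln.sequences.items()})
        try:
            pi = nucleotide_diversity(sub)
        except ValueError:
            pi = math.nan
        rows.append((start + 1, end, (start + 1 + end) / 2, pi))
        if end >= length:
            partial = end - start < window
            break
        start += step
    return DiversityProfile(gene=aln.name, window=window, step=step,
                            windows=rows, overall_pi=nucleotide_diversity(aln),
                            last_window_partial=partial)


def k2p_distance(a: str, b: str) -> DistanceResult:
    """Kimura 2-parameter distance between two aligned sequences.

    Saturation (a non-positive log argument) is flagged explicitly and the
    distance reported as NaN, never as a silent exception or -inf.
    """
    valid, ts, tv = pairwise_differences(a, b)
    P, Q = ts / valid, tv / valid
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        logger.warning("K2P saturated: P=%.4f Q=%.4f", P, Q)
        return DistanceResult(valid, P + Q, P, Q, math.nan, True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceResult(valid, P + Q, P, Q, d, False)


def mean_gene_distance(aln: GeneAlignment) -> float:
    """Overall mean K2P distance over all unordered taxon pairs.

    Saturated pairs are excluded with a warning rather than propagating NaN.
    """
    ds = []
    for ta, tb in combinations(aln.taxa, 2):
        res = k2p_distance(aln.sequences[ta], aln.sequences[tb])
        if res.saturated:
            logger.warning("%s: pair (%s, %s) saturated; excluded from mean",
                           aln.name, ta, tb)
            continue
        ds.append(res.d_k2p)
    if not ds:
        raise SaturationError(f"{aln.name}: every pair saturated")
    return float(np.mean(ds))


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str, code: GeneticCode) -> float:
    """Potential synonymous sites of a sense codon (fractional, 0..3).

    At each position the synonymous fraction is taken over the mutations
    that do not create a stop codon; mutations to stops are eliminated from
    consideration, so each codon still contributes exactly 3 sites in total
    (nonsynonymous = 3 - synonymous).
    """
    aa = code.translate(codon)
    syn = 0.0
    for i in range(3):
        n_syn = n_ok = 0
        for alt in NUCS:
            if alt == codon[i]:
                continue
            mut = codon[:i] + alt + codon[i + 1:]
            if code.is_stop(mut):
                continue
            n_ok += 1
            if code.translate(mut) == aa:
                n_syn += 1
        if n_ok:
            syn += n_syn / n_ok
    return syn


def _pathway_diffs(ca: str, cb: str, code: GeneticCode) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over minimal
    mutational pathways; pathways passing through a stop codon are excluded
    and the rest re-weighted equally.  If every pathway is blocked, all are
    used (degenerate corner, logged)."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in permutations(pos):
        cur, syn, nsyn, blocked = ca, 0, 0, False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1:]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.translate(cur) == code.translate(nxt):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if not blocked:
            paths.append((syn, nsyn))
    if not paths:
        logger.warning("all pathways %s->%s pass through stops; using all", ca, cb)
        for order in permutations(pos):
            cur, syn, nsyn = ca, 0, 0
            for i in order:
                nxt = cur[:i] + cb[i] + cur[i + 1:]
                if code.translate(cur) == code.translate(nxt):
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            paths.append((syn, nsyn))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"proportion {p:.4f} >= 3/4; correction undefined")
    return -0.75 * math.log(arg)


def nei_gojobori(a_cds: str, b_cds: str,
                 code: Optional[GeneticCode] = None) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks between two in-frame CDS of equal length.

    Codon pairs where either codon carries a non-ACGT symbol or is a stop
    codon are skipped.  Trailing incomplete codons are dropped.  Conventions:
    Ka == 0 gives ratio 0; Ks == 0 with Ka > 0 leaves the ratio undefined
    (flagged), never infinite.
    """
    code = code or vertebrate_mito_code()
    a_cds, b_cds = a_cds.upper(), b_cds.upper()
    if len(a_cds) != len(b_cds):
        raise ValueError("CDS lengths differ; align/trim first")
    n_codons = len(a_cds) // 3
    S_a = S_b = Sd = Nd = 0.0
    compared = 0
    for k in range(n_codons):
        ca, cb = a_cds[3 * k:3 * k + 3], b_cds[3 * k:3 * k + 3]
        if any(ch not in NUCS for ch in ca + cb):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            if k != n_codons - 1:
                logger.warning("stop codon inside CDS at codon %d; skipped", k)
            continue
        compared += 1
        S_a += _codon_site_counts(ca, code)
        S_b += _codon_site_counts(cb, code)
        if ca != cb:
            s, n = _pathway_diffs(ca, cb, code)
            Sd += s
            Nd += n
    if compared == 0:
        raise ValueError("no comparable codons")
    S = (S_a + S_b) / 2.0
    N = 3.0 * compared - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = False
    try:
        ks = _jc_correct(ps)
    except SaturationError:
        ks, saturated = math.nan, True
    try:
        ka = _jc_correct(pn)
    except SaturationError:
        ka, saturated = math.nan, True
    if saturated:
        return KaKsResult(S, N, Sd, Nd, ps, pn, ks, ka, math.nan, False,
                          compared, saturated=True)
    if ka == 0.0:
        ratio, defined = 0.0, True
    elif ks == 0.0:
        ratio, defined = math.nan, False
    else:
        ratio, defined = ka / ks, True
    return KaKsResult(S, N, Sd, Nd, ps, pn, ks, ka, ratio, defined, compared)


def mean_kaks(aln: GeneAlignment, code: Optional[GeneticCode] = None) -> KaKsResult:
    """Average NG86 quantities over all unordered pairs of a CDS alignment.

    Site and difference counts are averaged across pairs, then corrected —
    mirroring how a per-gene Ka/Ks is reported for a small clade.
    """
    code = code or vertebrate_mito_code()
    results = []
    for ta, tb in combinations(aln.taxa, 2):
        results.append(nei_gojobori(aln.sequences[ta], aln.sequences[tb], code))
    S = float(np.mean([r.syn_sites for r in results]))
    N = float(np.mean([r.nonsyn_sites for r in results]))
    Sd = float(np.mean([r.syn_diffs for r in results]))
    Nd = float(np.mean([r.nonsyn_diffs for r in results]))
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = False
    try:
        ks = _jc_correct(ps)
        ka = _jc_correct(pn)
    except SaturationError:
        ks = ka = math.nan
        saturated = True
    if saturated:
        ratio, defined = math.nan, False
    elif ka == 0.0:
        ratio, defined = 0.0, True
    elif ks == 0.0:
        ratio, defined = math.nan, False
    else:
        ratio, defined = ka / ks, True
    return KaKsResult(S, N, Sd, Nd, ps, pn, ks, ka, ratio, defined,
                      int(np.mean([r.codons_compared for r in results])),
                      saturated=saturated)
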