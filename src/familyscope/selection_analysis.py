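"""Homolog-pair detection and Nei-Gojobori (1986) Ka/Ks estimation.

The NG86 statistic counts, for an aligned codon pair, the numbers of
synonymous and nonsynonymous *sites* (each codon position contributes the
fraction of its three possible single-nucleotide changes that are
synonymous) and *differences* (averaged over all mutational orderings
between the two codons, excluding orderings that pass through a stop
codon).  Proportions pN = Nd/N and pS = Sd/S are Jukes-Cantor corrected,

    Ka = -(3/4) ln(1 - 4 pN / 3),   Ks likewise,

and the ratio Ka/Ks classifies selection: < 1 purifying, = 1 neutral,
> 1 positive.  The standard genetic code (translation table 1) is used;
mutations creating stop codons count as nonsynonymous in site counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from math import log

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger("familyscope")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
_NUCS = "ACGT"


@dataclass
class HomologPair:
    gene_a: str
    gene_b: str
    relationship: str  # paralog | ortholog
    identity: float  # global-alignment identity in [0, 1]
    aligned_codons: int


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float
    ks: float
    ratio: float | None  # None when Ks = 0 with Ka > 0
    selection_class: str  # purifying | neutral | positive | undefined
    compared_codons: int


def _check_sense(codon: str) -> None:
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} is not a sense codon")
    if codon not in CODON_TO_AA:
        raise ValueError(f"invalid codon {codon!r}")


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """NG86 (nonsynonymous, synonymous) site counts for one sense codon.

    Per position the synonymous fraction is the number of the 3 possible
    single-nucleotide changes that preserve the amino acid and do not
    create a stop codon, divided by 3.
    """
    _check_sense(codon)
    aa = CODON_TO_AA[codon]
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
        s_sites += syn / 3.0
    return 3.0 - s_sites, s_sites


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """NG86 (nonsynonymous, synonymous) difference counts for a codon pair.

    Steps along every mutational ordering between the codons are classified
    as synonymous or nonsynonymous and averaged; orderings passing through a
    stop codon are excluded.  If every ordering is blocked the unrestricted
    average is used and the third return value flags it.
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool):
        nd = sd = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            aa_from = CODON_TO_AA.get(current)
            aa_to = CODON_TO_AA.get(nxt)
            if aa_from == aa_to:
                sd += 1
            else:
                nd += 1
            current = nxt
        return nd, sd

    paths = [walk(order, False) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    blocked = not valid
    if blocked:
        valid = [walk(order, True) for order in permutations(diff_positions)]
    nd = sum(p[0] for p in valid) / len(valid)
    sd = sum(p[1] for p in valid) / len(valid)
    return nd, sd, blocked


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Align two CDS at codon resolution via their protein translations.

    Translations are globally aligned (BLOSUM62, gap open -10 / extend -0.5)
    and the gaps threaded back as codon triplets.  Columns containing a gap
    or an ambiguous base are dropped.
    """
    from .phylogeny import pairwise_align

    def codons_of(cds: str, label: str) -> list[str]:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"{label}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]  # terminal stop is not compared
        for idx, codon in enumerate(codons):
            if codon in STOP_CODONS:
                raise ValueError(f"{label}: internal stop codon at codon {idx + 1}")
        return codons

    codons_a = codons_of(cds_a, "cds_a")
    codons_b = codons_of(cds_b, "cds_b")
    prot_a = "".join(CODON_TO_AA.get(c, "X") for c in codons_a)
    prot_b = "".join(CODON_TO_AA.get(c, "X") for c in codons_b)
    row_a, row_b = pairwise_align(prot_a, prot_b)
    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            ib += 1
            continue
        if cb == "-":
            ia += 1
            continue
        codon_pair = (codons_a[ia], codons_b[ib])
        ia += 1
        ib += 1
        if any(nuc not in _NUCS for codon in codon_pair for nuc in codon):
            continue  # ambiguous bases are excluded from NG86
        pairs.append(codon_pair)
    return pairs


def classify_selection(ratio: float | None) -> str:
    """Selection class from a Ka/Ks ratio (exact comparison against 1)."""
    if ratio is None:
        return "undefined"
    if ratio < 1.0:
        return "purifying"
    if ratio > 1.0:
        return "positive"
    return "neutral"


def _jc_correct(p: float, label: str) -> float:
    if p >= 0.75:
        raise ValueError(
            f"{label} proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def compute_kaks(
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    min_codons: int = 30,
) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for an aligned CDS pair.

    Site counts are averaged over the two sequences.  Ka = 0 gives ratio 0
    (the convention of published paralog tables); Ks = 0 with Ka > 0 leaves
    the ratio undefined.
    """
    pairs = codon_align(cds_a, cds_b)
    if len(pairs) < min_codons:
        raise ValueError(
            f"only {len(pairs)} compared codons; need >= {min_codons}"
        )
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for ca, cb in pairs:
        na, sa = count_sites(ca)
        nb, sb = count_sites(cb)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s, _ = count_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    ka = _jc_correct(pn, "nonsynonymous") if pn > 0 else 0.0
    ks = _jc_correct(ps, "synonymous") if ps > 0 else 0.0
    if ka == 0.0:
        ratio: float | None = 0.0
    elif ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        gene_a=gene_a,
        gene_b=gene_b,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        ratio=ratio,
        selection_class=classify_selection(ratio),
        compared_codons=len(pairs),
    )


def _nucleotide_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def alignment_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -16.0,
    gap_extend: float = -4.0,
) -> float:
    """Identity (matches / alignment length) of a global nucleotide alignment.

    Affine gap costs are deliberately strong.  Under a cheap linear gap
    cost the mandatory gaps from any length difference float freely and
    harvest spurious matches, pushing the identity of *unrelated*
    codon-structured sequences to ~0.5, where a 40% homology floor stops
    discriminating.  With the defaults here unrelated CDS land at
    ~0.25-0.35 while genuine homologs stay far above 0.4.  All scores are
    exposed for tuning.
    """
    aligner = _nucleotide_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def find_homolog_pairs(
    set_a,
    set_b=None,
    min_length: int = 300,
    min_identity: float = 0.40,
) -> list[HomologPair]:
    """Identify paralogous (within-set) or orthologous (cross-set) CDS pairs.

    Sequences shorter than ``min_length`` bp are dropped.  Within one set
    every pair with global-alignment identity above ``min_identity`` is a
    paralog pair; across two sets only reciprocal best matches above the
    identity floor are kept as ortholog pairs.  Identity uses
    :func:`alignment_identity` (match +1 / mismatch -1, strong gap cost).
    """

    def keep_long(seqs):
        kept = [(r, s) for r, s in seqs if len(s) >= min_length]
        dropped = len(list(seqs)) - len(kept)
        if dropped:
            logger.info("find_homolog_pairs: dropped %d CDS shorter than %d bp",
                        dropped, min_length)
        return kept

    records_a = keep_long(list(set_a))
    if not records_a:
        warnings.warn("no sequences left after the length filter")
        return []

    def aligned_codon_count(sa: str, sb: str) -> int:
        try:
            return len(codon_align(sa, sb))
        except ValueError:
            return 0

    pairs: list[HomologPair] = []
    if set_b is None:
        for (ida, sa), (idb, sb) in combinations(records_a, 2):
            ident = alignment_identity(sa, sb)
            if ident > min_identity:
                pairs.append(
                    HomologPair(ida, idb, "paralog", ident, aligned_codon_count(sa, sb))
                )
        return pairs

    records_b = keep_long(list(set_b))
    if not records_b:
        warnings.warn("no sequences left after the length filter")
        return []
    ident = {
        (ida, idb): alignment_identity(sa, sb)
        for ida, sa in records_a
        for idb, sb in records_b
    }
    best_a = {
        ida: max(records_b, key=lambda rb: ident[(ida, rb[0])])[0]
        for ida, _ in records_a
    }
    best_b = {
        idb: max(records_a, key=lambda ra: ident[(ra[0], idb)])[0]
        for idb, _ in records_b
    }
    seq_a = dict(records_a)
    seq_b = dict(records_b)
    for ida, idb in best_a.items():
        if best_b[idb] == ida and ident[(ida, idb)] > min_identity:
            pairs.append(
                HomologPair(
                    ida,
                    idb,
                    "ortholog",
                    ident[(ida, idb)],
                    aligned_codon_count(seq_a[ida], seq_b[idb]),
                )
            )
    return pairs
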