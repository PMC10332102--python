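"""Domain scanning and AP2/ERF subfamily classification.

Family membership is decided by scanning protein translations with
position-specific scoring matrices (PSSMs) for the AP2 and B3 DNA-binding
domains and counting complete domain instances:

* two complete AP2 domains        -> AP2 subfamily
* one AP2 plus a complete B3      -> RAV subfamily
* exactly one complete AP2 domain -> ERF or DREB, split by the diagnostic
  residues at domain positions 14 and 19 (Ala/Asp -> ERF, Val/Glu -> DREB)
* no complete AP2 domain          -> excluded from the family

The bundled AP2 and B3 models are synthetic consensus constructs built for
this package (a PSSM scan carries the discriminative content needed here:
domain presence/count plus two diagnostic residues); results of a real
profile-HMM search can be imported through :func:`import_external_hits`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io_formats import ExternalDomainHitRow, SequenceSet

logger = logging.getLogger("familyscope")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Synthetic AP2-domain consensus, width 58; the diagnostic ERF/DREB positions
# are 14 and 19 (1-based within the domain).
AP2_CONSENSUS = (
    "SGYRGVRQRTWGK" "A" "VEIR" "D"
    "PRKGVRLWLGTFDTAEEAARAYDVAALKFRGPKAKTNFP"
)
assert len(AP2_CONSENSUS) == 58
assert AP2_CONSENSUS[13] == "A" and AP2_CONSENSUS[18] == "D"

# Synthetic B3-domain consensus, width 100.
B3_CONSENSUS = (
    "REVFEKTLTP" "SDVGKLNRLV" "IPKQHAERYF" "PLDSSNNQKG" "LLLNFEDRTG"
    "KVWRFRYSYW" "NSSQSYVLTK" "GWSRFVKEKN" "LRAGDVVSFQ" "RGVGDESERS"
)
assert len(B3_CONSENSUS) == 100


@dataclass
class DomainModel:
    """Per-position log-odds scores for one protein domain.

    ``matrix`` is ``width x 20`` (alphabet order ``ACDEFGHIKLMNPQRSTVWY``);
    ``frequencies`` are the per-position residue probabilities the log-odds
    were derived from (kept for sequence sampling). ``threshold`` is the
    minimum window score expressed as a fraction of the maximum attainable
    score (default 0.6).
    """

    name: str
    matrix: np.ndarray
    frequencies: np.ndarray
    threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("PSSM alphabet mismatch: expected 20 columns")
        if self.width < 10:
            raise ValueError("domain model width must be >= 10")
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("per-position frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def segment_max_score(self, lo: int, hi: int) -> float:
        """Maximum attainable score over model positions [lo, hi)."""
        return float(self.matrix[lo:hi].max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        match_prob: float = 0.95,
        threshold: float = 0.6,
        flat_positions: tuple[int, ...] = (),
    ) -> "DomainModel":
        """Build a model putting ``match_prob`` on each consensus residue.

        ``flat_positions`` (1-based) get uniform frequencies, i.e. carry no
        information - used for the ERF/DREB diagnostic positions, which
        legitimately differ between subfamilies and must not penalize
        either.
        """
        width = len(consensus)
        freqs = np.full((width, 20), (1.0 - match_prob) / 19.0)
        for pos, aa in enumerate(consensus):
            if pos + 1 in flat_positions:
                freqs[pos, :] = 0.05
            else:
                freqs[pos, :] = (1.0 - match_prob) / 19.0
                freqs[pos, _AA_INDEX[aa]] = match_prob
        matrix = np.log(freqs / 0.05)
        return cls(name=name, matrix=matrix, frequencies=freqs, threshold=threshold)

    def sample(self, rng: np.random.Generator, forced: dict[int, str] | None = None) -> str:
        """Sample one domain instance; ``forced`` maps 1-based positions to residues."""
        residues = [
            AMINO_ACIDS[rng.choice(20, p=self.frequencies[pos])]
            for pos in range(self.width)
        ]
        for pos1, aa in (forced or {}).items():
            residues[pos1 - 1] = aa
        return "".join(residues)


@lru_cache(maxsize=None)
def default_ap2_model() -> DomainModel:
    # positions 14/19 are the ERF/DREB diagnostics: scanned neutrally
    return DomainModel.from_consensus("AP2", AP2_CONSENSUS, flat_positions=(14, 19))


@lru_cache(maxsize=None)
def default_b3_model() -> DomainModel:
    return DomainModel.from_consensus("B3", B3_CONSENSUS)


@dataclass
class DomainHit:
    """One domain match on a protein; coordinates 1-based inclusive."""

    gene_id: str
    domain_name: str
    start: int
    end: int
    score: float
    complete: bool

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class FamilyAssignment:
    gene_id: str
    subfamily: str  # ERF | DREB | AP2 | RAV | excluded
    diagnostic: tuple[str, str] | None = None  # residues at domain pos 14, 19
    ambiguous_flag: bool = False
    n_ap2: int = 0
    has_b3: bool = False


def _encode(protein: str) -> np.ndarray:
    """Residues to alphabet indices; unknown residues (incl. 'X') -> -1."""
    codes = np.fromiter(
        (_AA_INDEX.get(aa, -1) for aa in protein), dtype=np.int64, count=len(protein)
    )
    unknown = sorted({aa for aa in protein if aa not in _AA_INDEX and aa != "X"})
    if unknown:
        warnings.warn(
            f"unknown residues {unknown} scored with background frequency"
        )
    return codes


def _segment_scores(matrix: np.ndarray, codes: np.ndarray) -> float:
    """Score one window; unknown residues contribute the background log-odds (0)."""
    mask = codes >= 0
    return float(matrix[np.arange(len(codes))[mask], codes[mask]].sum())


def scan_domains(
    protein: str,
    model: DomainModel,
    gene_id: str = "",
    min_partial: int = 10,
) -> list[DomainHit]:
    """Slide ``model`` over ``protein`` and report non-overlapping hits.

    Complete hits are full-width windows scoring at least
    ``threshold * max_score``, selected greedily best-first.  Matches cut by
    the sequence ends (a domain prefix at the C-terminus or suffix at the
    N-terminus) that clear the same fractional threshold on their covered
    model positions are reported with ``complete=False``.
    """
    codes = _encode(protein)
    length = len(codes)
    width = model.width
    hits: list[DomainHit] = []

    if length >= width:
        # vectorized full-window scoring
        windows = np.lib.stride_tricks.sliding_window_view(codes, width)
        mask = windows >= 0
        gathered = np.where(
            mask, model.matrix[np.arange(width)[None, :], np.where(mask, windows, 0)], 0.0
        )
        scores = gathered.sum(axis=1)
        cutoff = model.threshold * model.max_score
        order = np.argsort(-scores, kind="stable")  # ties -> lower start first
        for idx in order:
            if scores[idx] < cutoff:
                break
            hit = DomainHit(
                gene_id=gene_id,
                domain_name=model.name,
                start=int(idx) + 1,
                end=int(idx) + width,
                score=float(scores[idx]),
                complete=True,
            )
            if not any(hit.overlaps(h) for h in hits):
                hits.append(hit)

    # terminal partial matches (domain truncated by the sequence boundary)
    max_k = min(width - 1, length)
    for k in range(max_k, min_partial - 1, -1):
        # model suffix aligned flush with the sequence start
        seg = _segment_scores(model.matrix[width - k :], codes[:k])
        if seg >= model.threshold * model.segment_max_score(width - k, width):
            hit = DomainHit(gene_id, model.name, 1, k, seg, complete=False)
            if not any(hit.overlaps(h) for h in hits):
                hits.append(hit)
            break
    for k in range(max_k, min_partial - 1, -1):
        # model prefix aligned flush with the sequence end
        seg = _segment_scores(model.matrix[:k], codes[length - k :])
        if seg >= model.threshold * model.segment_max_score(0, k):
            hit = DomainHit(
                gene_id, model.name, length - k + 1, length, seg, complete=False
            )
            if not any(hit.overlaps(h) for h in hits):
                hits.append(hit)
            break

    hits.sort(key=lambda h: h.start)
    return hits


def classify_subfamily(
    hits: list[DomainHit], protein: str, gene_id: str = ""
) -> FamilyAssignment:
    """Assign ERF/DREB/AP2/RAV (or exclusion) from domain hits.

    Genes without a complete AP2 domain are excluded; two or more complete
    AP2 hits make the AP2 subfamily; one AP2 plus a complete B3 makes RAV;
    a single AP2 is split into ERF/DREB by the residues at domain positions
    14 and 19.  Mixed diagnostics fall back to position 14 alone with
    ``ambiguous_flag`` set.
    """
    ap2 = [h for h in hits if h.domain_name == "AP2" and h.complete]
    b3 = [h for h in hits if h.domain_name == "B3" and h.complete]
    for a in ap2:
        for b in b3:
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping AP2 and B3 hits on {gene_id or 'protein'}: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )
    n_ap2 = len(ap2)
    has_b3 = bool(b3)
    if n_ap2 == 0:
        return FamilyAssignment(gene_id, "excluded", None, False, 0, has_b3)
    if n_ap2 >= 2:
        return FamilyAssignment(gene_id, "AP2", None, False, n_ap2, has_b3)
    if has_b3:
        return FamilyAssignment(gene_id, "RAV", None, False, 1, True)
    hit = ap2[0]
    res14 = protein[hit.start - 1 + 13]
    res19 = protein[hit.start - 1 + 18]
    if (res14, res19) == ("A", "D"):
        return FamilyAssignment(gene_id, "ERF", ("A", "D"), False, 1, False)
    if (res14, res19) == ("V", "E"):
        return FamilyAssignment(gene_id, "DREB", ("V", "E"), False, 1, False)
    # mixed diagnostics: position 14 dominates, flagged as ambiguous
    if res14 == "V":
        return FamilyAssignment(gene_id, "DREB", (res14, res19), True, 1, False)
    return FamilyAssignment(gene_id, "ERF", (res14, res19), True, 1, False)


@dataclass
class ProteinProperties:
    orf_length: int  # bp, including the stop codon
    protein_length: int  # aa
    molecular_weight: float  # Da, average isotopic masses
    isoelectric_point: float  # pH units


def protein_molecular_weight(protein: str) -> float:
    """Average-mass molecular weight of a peptide (Da), water included."""
    return float(ProteinAnalysis(protein).molecular_weight())


def protein_isoelectric_point(protein: str) -> float:
    """Isoelectric point via charge bisection with the Bjellqvist pKa set."""
    return float(ProteinAnalysis(protein).isoelectric_point())


def compute_protein_properties(cds: str) -> ProteinProperties:
    """ORF length, protein length, MW and pI for a stop-terminated ORF."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    translation = str(Seq(cds).translate())
    if not translation.endswith("*"):
        raise ValueError("CDS does not end with a stop codon")
    body = translation[:-1]
    if "*" in body:
        codon_pos = body.index("*") + 1
        raise ValueError(f"internal stop codon at codon {codon_pos}")
    return ProteinProperties(
        orf_length=len(cds),
        protein_length=len(body),
        molecular_weight=protein_molecular_weight(body),
        isoelectric_point=protein_isoelectric_point(body),
    )


def import_external_hits(
    rows: list[ExternalDomainHitRow],
    models: dict[str, DomainModel],
    proteins: SequenceSet,
) -> list[DomainHit]:
    """Convert external (HMMER-style) envelope rows to :class:`DomainHit`.

    A hit is ``complete`` iff its envelope covers at least 90% of the model
    width.  Rows referencing unknown genes are a hard error.
    """
    hits: list[DomainHit] = []
    for row in rows:
        if row.gene_id not in proteins:
            raise ValueError(f"external hit references unknown gene {row.gene_id!r}")
        if row.domain_name not in models:
            raise ValueError(f"no domain model named {row.domain_name!r}")
        width = models[row.domain_name].width
        coverage = (row.env_end - row.env_start + 1) / width
        hits.append(
            DomainHit(
                gene_id=row.gene_id,
                domain_name=row.domain_name,
                start=row.env_start,
                end=row.env_end,
                score=row.score,
                complete=coverage >= 0.9,
            )
        )
    return hits


def identify_family(
    proteins: SequenceSet,
    ap2_model: DomainModel | None = None,
    b3_model: DomainModel | None = None,
    external_hits: list[DomainHit] | None = None,
) -> dict[str, FamilyAssignment]:
    """Scan and classify every protein in a set; returns id -> assignment."""
    ap2_model = ap2_model or default_ap2_model()
    b3_model = b3_model or default_b3_model()
    assignments: dict[str, FamilyAssignment] = {}
    by_gene: dict[str, list[DomainHit]] = {}
    if external_hits is not None:
        for hit in external_hits:
            by_gene.setdefault(hit.gene_id, []).append(hit)
    for gene_id, protein in proteins:
        if external_hits is not None:
            hits = by_gene.get(gene_id, [])
        else:
            hits = scan_domains(protein, ap2_model, gene_id) + scan_domains(
                protein, b3_model, gene_id
            )
        assignments[gene_id] = classify_subfamily(hits, protein, gene_id)
    counts: dict[str, int] = {}
    for a in assignments.values():
        counts[a.subfamily] = counts.get(a.subfamily, 0) + 1
    logger.info("identify_family: %d proteins -> %s", len(proteins), counts)
    return assignments
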