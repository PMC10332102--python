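"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline can be exercised without real
transcriptome downloads: this module plants AP2/B3 domains (with the
ERF/DREB diagnostic residues) into otherwise random proteins, evolves CDS
pairs under a controlled dN/dS, simulates FPKM matrices with planted fold
changes and latent-factor co-expression modules, and writes qRT-PCR Ct
tables with planted treatment responses.  Each generator returns a truth
table covering every generated entity, and is deterministic under a fixed
seed.

Reverse translation uses uniform synonymous codon choice (no codon bias),
which keeps NG86 site counts unbiased - the simplest null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family_identification import (
    AMINO_ACIDS,
    DomainModel,
    default_ap2_model,
    default_b3_model,
)
from .io_formats import NUCLEOTIDE, PROTEIN, SequenceSet, TabularMatrix
from .selection_analysis import CODON_TO_AA, STOP_CODONS, count_sites

logger = logging.getLogger("familyscope")

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(STOP_CODONS)

ERF_DIAGNOSTIC = {14: "A", 19: "D"}
DREB_DIAGNOSTIC = {14: "V", 19: "E"}

DREB_CLANS = tuple(f"A{i}" for i in range(1, 7))
ERF_CLANS = tuple(f"B{i}" for i in range(1, 7))


@dataclass
class TruthTable:
    """Ground truth for generated entities (exhaustive by construction)."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    de: pd.DataFrame = field(default_factory=pd.DataFrame)
    modules: pd.DataFrame = field(default_factory=pd.DataFrame)
    references: SequenceSet | None = None
    reference_clans: dict[str, str] = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform-synonymous-codon CDS for a protein, stop codon appended."""
    codons = [
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random stop-free CDS of ``n_codons`` sense codons starting with ATG."""
    sense = sorted(CODON_TO_AA)
    codons = ["ATG"] + [sense[rng.integers(0, len(sense))] for _ in range(n_codons - 1)]
    return "".join(codons)


def _mutate_protein(
    protein: str, rate: float, rng: np.random.Generator, keep: set[int]
) -> str:
    """Point-mutate each position (0-based, outside ``keep``) with prob ``rate``."""
    residues = list(protein)
    for pos in range(1, len(residues)):  # keep the initial Met
        if pos in keep:
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(residues[pos], "")
            residues[pos] = choices[rng.integers(0, len(choices))]
    return "".join(residues)


def generate_transcriptome(
    seed,
    n_erf: int = 20,
    n_dreb: int = 10,
    n_ap2: int = 6,
    n_rav: int = 4,
    n_negative: int = 10,
    n_incomplete: int = 5,
    ap2_model: DomainModel | None = None,
    b3_model: DomainModel | None = None,
    clan_mutation_rate: float = 0.03,
    with_references: bool = True,
) -> tuple[SequenceSet, SequenceSet, TruthTable]:
    """Generate CDS + protein sets for a synthetic AP2/ERF transcriptome.

    ERF/DREB genes carry exactly one planted AP2 domain (diagnostic residues
    Ala/Asp resp. Val/Glu at domain positions 14 and 19) and descend from
    one of six clan ancestors each (B1-B6 resp. A1-A6) by point mutation;
    AP2-subfamily genes carry two AP2 instances; RAV genes one AP2 plus one
    B3; "incomplete" decoys a 50%-width AP2 fragment at the C-terminus;
    negatives none.  The ancestors are returned as a labelled clan
    reference set.
    """
    for count in (n_erf, n_dreb, n_ap2, n_rav, n_negative, n_incomplete):
        if count < 0:
            raise ValueError("gene counts must be >= 0")
    rng = _rng(seed)
    ap2_model = ap2_model or default_ap2_model()
    b3_model = b3_model or default_b3_model()
    if ap2_model.width < 19:
        raise ValueError("AP2 model too narrow for diagnostic positions 14/19")

    proteins: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    def make_single_domain_ancestor(diagnostic: dict[int, str]) -> tuple[str, int]:
        flank1 = _random_protein(rng, int(rng.integers(40, 91)))
        flank2 = _random_protein(rng, int(rng.integers(50, 121)))
        domain = ap2_model.sample(rng, forced=diagnostic)
        ancestor = "M" + flank1 + domain + flank2
        return ancestor, 2 + len(flank1)  # 1-based domain start

    # clan ancestors double as the labelled reference set; each carries a
    # fixed codon assignment so same-clan members share CDS-level ancestry
    ancestors: dict[str, tuple[str, int, list[str]]] = {}
    for clan in ERF_CLANS:
        anc, dom_start = make_single_domain_ancestor(ERF_DIAGNOSTIC)
        codons = [_AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))]
                  for aa in anc]
        ancestors[clan] = (anc, dom_start, codons)
    for clan in DREB_CLANS:
        anc, dom_start = make_single_domain_ancestor(DREB_DIAGNOSTIC)
        codons = [_AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))]
                  for aa in anc]
        ancestors[clan] = (anc, dom_start, codons)

    member_codons: dict[str, list[str]] = {}

    def add_single_domain_genes(subfamily: str, clans, count: int, prefix: str):
        for i in range(count):
            clan = clans[i % len(clans)]
            anc, dom_start, anc_codons = ancestors[clan]
            # the domain is conserved within a clan; only flanks diverge
            keep = set(range(dom_start - 1, dom_start - 1 + ap2_model.width))
            protein = _mutate_protein(anc, clan_mutation_rate, rng, keep)
            gene_id = f"{prefix}{i + 1:03d}"
            # inherit the ancestor codon wherever the residue is unchanged,
            # plus sparse synonymous substitutions -> realistic low-dS paralogs
            codons = []
            for pos, aa in enumerate(protein):
                if aa == anc[pos]:
                    codon = anc_codons[pos]
                    if rng.random() < clan_mutation_rate and len(_AA_TO_CODONS[aa]) > 1:
                        others = [c for c in _AA_TO_CODONS[aa] if c != codon]
                        codon = others[rng.integers(0, len(others))]
                else:
                    codon = _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))]
                codons.append(codon)
            member_codons[gene_id] = codons
            proteins.append((gene_id, protein))
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "subfamily": subfamily,
                    "clan": clan,
                    "domain_starts": str(dom_start),
                    "res14": protein[dom_start - 1 + 13],
                    "res19": protein[dom_start - 1 + 18],
                }
            )

    add_single_domain_genes("ERF", ERF_CLANS, n_erf, "ERF")
    add_single_domain_genes("DREB", DREB_CLANS, n_dreb, "DREB")

    for i in range(n_ap2):
        f1 = _random_protein(rng, int(rng.integers(30, 81)))
        f2 = _random_protein(rng, int(rng.integers(20, 61)))
        f3 = _random_protein(rng, int(rng.integers(30, 81)))
        d1 = ap2_model.sample(rng)
        d2 = ap2_model.sample(rng)
        protein = "M" + f1 + d1 + f2 + d2 + f3
        start1 = 2 + len(f1)
        start2 = start1 + ap2_model.width + len(f2)
        gene_id = f"AP2-{i + 1:03d}"
        proteins.append((gene_id, protein))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "subfamily": "AP2",
                "clan": "AP2",
                "domain_starts": f"{start1};{start2}",
                "res14": "",
                "res19": "",
            }
        )

    for i in range(n_rav):
        f1 = _random_protein(rng, int(rng.integers(20, 61)))
        f2 = _random_protein(rng, int(rng.integers(15, 41)))
        f3 = _random_protein(rng, int(rng.integers(20, 61)))
        ap2_dom = ap2_model.sample(rng)
        b3_dom = b3_model.sample(rng)
        protein = "M" + f1 + ap2_dom + f2 + b3_dom + f3
        start1 = 2 + len(f1)
        start2 = start1 + ap2_model.width + len(f2)
        gene_id = f"RAV{i + 1:03d}"
        proteins.append((gene_id, protein))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "subfamily": "RAV",
                "clan": "RAV",
                "domain_starts": f"{start1};{start2}",
                "res14": "",
                "res19": "",
            }
        )

    for i in range(n_negative):
        protein = "M" + _random_protein(rng, int(rng.integers(150, 351)))
        gene_id = f"NEG{i + 1:03d}"
        proteins.append((gene_id, protein))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "subfamily": "negative",
                "clan": "",
                "domain_starts": "",
                "res14": "",
                "res19": "",
            }
        )

    frag_len = ap2_model.width // 2  # < 60% of the model width
    for i in range(n_incomplete):
        flank = _random_protein(rng, int(rng.integers(80, 201)))
        fragment = ap2_model.sample(rng)[:frag_len]
        protein = "M" + flank + fragment  # domain prefix cut by the C-terminus
        gene_id = f"INC{i + 1:03d}"
        proteins.append((gene_id, protein))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "subfamily": "incomplete",
                "clan": "",
                "domain_starts": str(len(protein) - frag_len + 1),
                "res14": "",
                "res19": "",
            }
        )

    cds_records = []
    for gid, p in proteins:
        if gid in member_codons:
            stop = _STOPS[rng.integers(0, len(_STOPS))]
            cds_records.append((gid, "".join(member_codons[gid]) + stop))
        else:
            cds_records.append((gid, reverse_translate(p, rng)))
    truth = TruthTable(genes=pd.DataFrame(truth_rows))
    if with_references:
        truth.references = SequenceSet(
            [(f"REF_{clan}", anc) for clan, (anc, _, _) in sorted(ancestors.items())],
            PROTEIN,
        )
        truth.reference_clans = {f"REF_{clan}": clan for clan in ancestors}
    logger.info(
        "generate_transcriptome: %d genes (seed-controlled), %d reference ancestors",
        len(proteins),
        len(truth.reference_clans),
    )
    return (
        SequenceSet(cds_records, NUCLEOTIDE) if cds_records else SequenceSet([], NUCLEOTIDE),
        SequenceSet(proteins, PROTEIN) if proteins else SequenceSet([], PROTEIN),
        truth,
    )


def evolve_pair(
    cds: str,
    omega: float,
    ds_target: float,
    seed,
    max_proposals: int | None = None,
) -> tuple[str, tuple[int, int]]:
    """Evolve a CDS copy until its synonymous divergence reaches a target.

    Uniform random single-nucleotide changes are proposed; proposals
    creating stop codons are rejected, synonymous proposals accepted with
    probability 1 and nonsynonymous ones with probability ``omega``.  The
    walk stops once the number of *accepted* synonymous events reaches
    ``round(ds_target * S)`` where S is the NG86 synonymous site count of
    the ancestor, so dS is controlled directly rather than through
    proposal counts.  Returns the derived CDS and the realized accepted
    (synonymous, nonsynonymous) event counts.
    """
    if omega < 0 or omega > 1.5:
        raise ValueError("omega must be in [0, 1.5]")
    if ds_target < 0 or ds_target >= 1.5:
        raise ValueError("ds_target must be in [0, 1.5)")
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    rng = _rng(seed)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    terminal_stop = ""
    if codons and codons[-1] in STOP_CODONS:
        terminal_stop = codons.pop()
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {idx + 1}")

    s_sites = sum(count_sites(c)[1] for c in codons)
    target = int(round(ds_target * s_sites))
    if target == 0:
        return "".join(codons) + terminal_stop, (0, 0)

    if max_proposals is None:
        max_proposals = max(100_000, 5_000 * target)
    n_nt = 3 * len(codons)
    syn_accepted = nonsyn_accepted = 0
    accept_nonsyn = min(1.0, omega)
    for _ in range(max_proposals):
        site = int(rng.integers(0, n_nt))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        current = codon[pos]
        new = "ACGT".replace(current, "")[rng.integers(0, 3)]
        mutant = codon[:pos] + new + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
            codons[ci] = mutant
            syn_accepted += 1
            if syn_accepted >= target:
                return "".join(codons) + terminal_stop, (syn_accepted, nonsyn_accepted)
        elif rng.random() < accept_nonsyn:
            codons[ci] = mutant
            nonsyn_accepted += 1
    raise RuntimeError(
        f"synonymous target {target} not reached within {max_proposals} proposals; "
        "sequence may be too short"
    )


def generate_divergent_pairs(
    seed,
    n_pairs: int = 5,
    omega: float = 0.2,
    ds_target: float = 0.3,
    n_codons: int = 300,
) -> tuple[SequenceSet, pd.DataFrame]:
    """Ancestor/derived CDS pairs with controlled dN/dS and dS."""
    rng = _rng(seed)
    records: list[tuple[str, str]] = []
    rows: list[dict] = []
    for i in range(n_pairs):
        ancestor = random_cds(rng, n_codons)
        derived, (syn, nonsyn) = evolve_pair(ancestor, omega, ds_target, rng)
        id_a, id_b = f"PAIR{i + 1:02d}a", f"PAIR{i + 1:02d}b"
        records.append((id_a, ancestor))
        records.append((id_b, derived))
        rows.append(
            {
                "gene_a": id_a,
                "gene_b": id_b,
                "omega": omega,
                "ds_target": ds_target,
                "syn_events": syn,
                "nonsyn_events": nonsyn,
            }
        )
    return SequenceSet(records, NUCLEOTIDE), pd.DataFrame(rows)


def generate_expression(
    seed,
    gene_ids: list[str] | None = None,
    n_genes: int = 40,
    groups: tuple[str, ...] = ("M1", "M2", "M3", "F1", "F2", "F3"),
    n_replicates: int = 3,
    baseline_range: tuple[float, float] = (2.0, 8.0),
    sigma: float = 0.1,
    de_specs: dict[str, tuple[str, float]] | None = None,
    modules: list[list[str]] | None = None,
    module_loading: float = 0.998,
    module_scale: float = 1.5,
) -> tuple[TabularMatrix, TruthTable]:
    """Simulate a genes x samples FPKM matrix.

    Log2 FPKM is Normal(mu_g, sigma) within replicates (log-normal FPKM
    noise, which makes t tests on the log scale well-behaved).  Planted DE
    genes (``de_specs``: gene -> (group, fold)) are shifted by log2(fold)
    in their designated group.  Module members share a per-group latent
    factor with the given loading, so their pairwise correlation across
    group means approaches loading**2; non-members are flat and
    independent.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rng = _rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    de_specs = de_specs or {}
    modules = modules or []
    for gene, (group, fold) in de_specs.items():
        if fold <= 0:
            raise ValueError(f"fold change for {gene} must be > 0")
        if group not in groups:
            raise ValueError(f"unknown group {group!r} for DE gene {gene}")
    module_of: dict[str, int] = {}
    for m_idx, members in enumerate(modules):
        for gene in members:
            if gene in module_of:
                raise ValueError(f"gene {gene} assigned to two modules")
            module_of[gene] = m_idx

    n_g = len(groups)
    baselines = rng.uniform(*baseline_range, size=len(gene_ids))
    latents = rng.normal(size=(len(modules), n_g))  # per-module per-group factor
    resid = np.sqrt(max(0.0, 1.0 - module_loading**2))

    columns = [f"{g}_{r + 1}" for g in groups for r in range(n_replicates)]
    col_groups = {f"{g}_{r + 1}": g for g in groups for r in range(n_replicates)}
    log2x = np.empty((len(gene_ids), n_g * n_replicates))
    for gi, gene in enumerate(gene_ids):
        group_mean = np.full(n_g, baselines[gi])
        if gene in module_of:
            eps = rng.normal(size=n_g)
            group_mean = group_mean + module_scale * (
                module_loading * latents[module_of[gene]] + resid * eps
            )
        if gene in de_specs:
            group, fold = de_specs[gene]
            group_mean[groups.index(group)] += np.log2(fold)
        noise = rng.normal(scale=sigma, size=(n_g, n_replicates))
        log2x[gi] = (group_mean[:, None] + noise).ravel()

    fpkm = pd.DataFrame(
        np.power(2.0, log2x), index=gene_ids, columns=columns
    )
    matrix = TabularMatrix.from_frame(fpkm, col_groups)
    truth = TruthTable(
        de=pd.DataFrame(
            [
                {"gene_id": g, "group": grp, "fold": fold}
                for g, (grp, fold) in de_specs.items()
            ]
        ),
        modules=pd.DataFrame(
            [
                {"module": m_idx, "gene_id": g}
                for m_idx, members in enumerate(modules)
                for g in members
            ]
        ),
    )
    return matrix, truth


def generate_ct_tables(
    seed,
    genes: tuple[str, ...] = ("Q1", "Q2", "Q3"),
    treatments: tuple[str, ...] = ("ABA",),
    timepoints: tuple[int, ...] = (0, 1, 3, 6, 12, 24),
    n_replicates: int = 3,
    fold_profiles: dict[tuple[str, str], dict[int, float]] | None = None,
    ref_mean: float = 20.0,
    ref_sd: float = 0.1,
    noise_sd: float = 0.15,
    baseline_range: tuple[float, float] = (24.0, 28.0),
) -> pd.DataFrame:
    """Simulate a qRT-PCR Ct table with planted treatment responses.

    The reference gene's Ct is Normal(20, 0.1) irrespective of condition;
    the target Ct is its per-gene baseline minus log2 of the planted fold
    at that timepoint, plus Normal(0, 0.15) noise; 3 biological replicates
    per cell by default.  Timepoint 0 h (the calibrator) is mandatory.
    """
    if 0 not in timepoints:
        raise ValueError("missing 0 h calibrator timepoint")
    rng = _rng(seed)
    fold_profiles = fold_profiles or {}
    rows: list[dict] = []
    for gene in genes:
        for treatment in treatments:
            baseline = rng.uniform(*baseline_range)
            profile = fold_profiles.get((gene, treatment), {})
            for tp in timepoints:
                fold = profile.get(tp, 1.0)
                if fold <= 0:
                    raise ValueError("planted fold must be > 0")
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "gene_id": gene,
                            "treatment": treatment,
                            "timepoint": tp,
                            "replicate": rep,
                            "ct_target": baseline
                            - np.log2(fold)
                            + rng.normal(scale=noise_sd),
                            "ct_reference": rng.normal(ref_mean, ref_sd),
                        }
                    )
    return pd.DataFrame(rows)
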