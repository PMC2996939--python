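"""Synthetic genomes, gene models, proteomes, phosphosites, SNPs, domains
and term annotations with the statistical structure the analysis assumes,
plus planted ground truth for recovery tests.

The generator emulates desk-scale versions of the real inputs: a residue
composition close to a plant proteome, log-normal protein lengths,
per-residue phosphorylation probabilities tuned so the expected site split
is roughly 70.7/20.7/8.6 across S/T/Y, SNPs at a plant-like per-coding-base
rate shared across accessions, and multi-exon genes on both strands so the
splice/strand arithmetic is genuinely exercised.

Planting is constructive rather than rejection-sampled: gain/loss events are
realised by writing a designed 17-residue context cassette into the protein
and engineering the single-base SNP that flips the toy prediction score
across its high-confidence bands, so every requested event is feasible by
construction (verified against the scorer at plant time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_effects import CODONS_OF
from .core_io import (
    PHOSPHO_RESIDUES,
    GeneModel,
    PhosphoSite,
    ProteinRecord,
    SnpRecord,
    write_domains,
    write_fasta,
    write_gene_models,
    write_sites,
    write_snps,
    write_terms,
    DomainAnnotation,
    TermAnnotation,
)
from .gain_loss import toy_scorer
from .variant_mapping import cds_to_genomic, revcomp

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Default residue composition (plant-proteome-like, sums to 1).
DEFAULT_COMPOSITION = {
    "A": 0.078, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.062, "G": 0.071, "H": 0.023, "I": 0.053,
    "L": 0.085, "K": 0.064, "M": 0.024, "F": 0.040, "P": 0.047,
    "S": 0.090, "T": 0.051, "W": 0.012, "Y": 0.029, "V": 0.069,
}

#: Per-residue phosphorylation probabilities.  With the default composition
#: these give an expected site split of ~70.7% pS / 20.7% pT / 8.6% pY.
DEFAULT_PHOSPHO_PROB = {"S": 0.08, "T": 0.04133, "Y": 0.03020}

STOP_CODONS = ("TAA", "TAG", "TGA")


class SimulationConfigError(ValueError):
    """Invalid or infeasible simulation request."""


@dataclass(frozen=True)
class PlantedHotspot:
    protein_index: int
    start: int
    winsize: int
    n_sites: int


@dataclass(frozen=True)
class PlantedGainLoss:
    kind: str  # loss | gain
    status: int  # 1 | 2


@dataclass(frozen=True)
class PlantedSubstitution:
    """Excess of one substitution at phosphosites of one residue type."""

    from_residue: str
    to_residue: str
    base_rate: float
    factor: float


@dataclass
class SimulationConfig:
    n_proteins: int = 100
    length_log_mean: float = float(np.log(220.0))
    length_log_sigma: float = 0.45
    min_length: int = 40
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    phospho_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHOSPHO_PROB)
    )
    snp_rate: float = 0.008
    n_accessions: int = 20
    allele_sharing_prob: float = 0.2
    max_exons: int = 4
    intron_length: tuple[int, int] = (30, 120)
    n_chromosomes: int = 2
    domain_coverage: float = 0.25
    domain_length: tuple[int, int] = (30, 80)
    n_terms: int = 20
    term_base_rate: float = 0.10
    term_enrichment: tuple[str, tuple[str, ...], float] | None = None
    planted_hotspots: tuple[PlantedHotspot, ...] = ()
    planted_gain_loss: tuple[PlantedGainLoss, ...] = ()
    planted_substitution: PlantedSubstitution | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in list(self.phospho_prob.values()) + [
            self.snp_rate, self.allele_sharing_prob, self.term_base_rate
        ]:
            if not (0.0 <= prob <= 1.0):
                raise SimulationConfigError(f"probability {prob} outside [0, 1]")
        if not (0.0 <= self.domain_coverage <= 1.0):
            raise SimulationConfigError("domain coverage must be in [0, 1]")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise SimulationConfigError(f"composition sums to {total}, not 1")
        for ph in self.planted_hotspots:
            if ph.n_sites > ph.winsize:
                raise SimulationConfigError(
                    f"planted hotspot wants {ph.n_sites} sites in a window of "
                    f"{ph.winsize}"
                )
        if len(self.planted_gain_loss) > self.n_proteins:
            raise SimulationConfigError("more planted events than proteins")


# ---------------------------------------------------------------------------
# Cassettes for planted gain/loss events
# ---------------------------------------------------------------------------

CASSETTE_HALF = 8  # cassette spans center-8 .. center+8 (17 residues)

# offset -> residue, relative to the cassette center; unlisted offsets are 'A'
_CASSETTE_LAYOUT = {
    ("loss", 2): ({0: "S", 1: "R", 2: "K"}, (0, "S", "P")),
    ("gain", 2): ({0: "A", 1: "R", 2: "K"}, (0, "A", "S")),
    ("loss", 1): ({0: "S", 1: "R", -3: "D"}, (1, "R", "P")),
    ("gain", 1): ({0: "S", 1: "P", -3: "D"}, (1, "P", "R")),
}


def _single_base_change(ref_aa: str, alt_aa: str) -> tuple[str, str, int]:
    """A codon pair (ref, alt) differing in exactly one base, plus its index."""
    for ref_codon in CODONS_OF[ref_aa]:
        for alt_codon in CODONS_OF[alt_aa]:
            diff = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
            if len(diff) == 1:
                return ref_codon, alt_codon, diff[0]
    raise SimulationConfigError(
        f"no single-base codon change realises {ref_aa} -> {alt_aa}"
    )


@dataclass
class _PlantedSnpSpec:
    """Internal: an engineered SNP to emit, with its expected event."""

    protein_index: int
    aa_pos: int  # 1-based residue whose codon changes
    ref_codon: str
    alt_codon: str
    base_index: int  # 0-based within the codon
    event: dict  # expected GainLossEvent fields


@dataclass
class SimulatedData:
    """Everything one simulation run produced, plus its ground truth."""

    config: SimulationConfig
    proteins: dict[str, ProteinRecord]
    proteome: dict[str, str]
    models: dict[str, GeneModel]
    genome: dict[str, str]
    cds_by_gene: dict[str, str]
    sites_experimental: list[PhosphoSite] = field(default_factory=list)
    sites_predicted: list[PhosphoSite] = field(default_factory=list)
    predicted_scores: dict[str, dict[int, float]] = field(default_factory=dict)
    snps: list[SnpRecord] = field(default_factory=list)
    domains: list[DomainAnnotation] = field(default_factory=list)
    terms: list[TermAnnotation] = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    _planted_specs: list[_PlantedSnpSpec] = field(default_factory=list)
    _snp_exclude: dict[str, set[int]] = field(default_factory=dict)

    def write_outputs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fasta", self.genome)
        write_fasta(out / "proteome.fasta", self.proteome)
        write_gene_models(out / "genes.gff3", self.models.values())
        write_sites(out / "sites.tsv", self.sites_experimental + self.sites_predicted)
        write_snps(out / "snps.tsv", self.snps)
        write_domains(out / "domains.tsv", self.domains)
        write_terms(out / "terms.tsv", self.terms)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Proteome + genome generation
# ---------------------------------------------------------------------------


def generate_proteome(config: SimulationConfig) -> SimulatedData:
    """Sample a proteome and build a genome whose gene models encode it.

    Proteins are drawn from the residue composition; planted-hotspot windows
    are rewritten to guarantee enough S/T/Y capacity, and planted gain/loss
    events get their context cassettes written in.  The CDS of each protein
    is built by sampling synonymous codons (plus a stop codon), split into
    exons with intron spacers, placed on alternating strands, and assembled
    into chromosome sequences.  Every gene round-trips: the spliced,
    strand-oriented CDS translates back to the protein (+ terminal stop).
    """
    rng = np.random.default_rng([config.seed, 0])
    aa_list = list(AA_ORDER)
    probs = np.array([config.composition[a] for a in aa_list])
    lengths = np.exp(
        rng.normal(config.length_log_mean, config.length_log_sigma,
                   size=config.n_proteins)
    ).astype(int)
    lengths = np.maximum(lengths, config.min_length)

    sequences = [
        list(rng.choice(aa_list, size=length, p=probs)) for length in lengths
    ]

    # guarantee planted-hotspot windows have enough S/T/Y capacity
    for ph in config.planted_hotspots:
        seq = sequences[ph.protein_index]
        if ph.start < 1 or ph.start + ph.winsize - 1 > len(seq):
            raise SimulationConfigError(
                f"planted hotspot window outside protein {ph.protein_index}"
            )
        window = range(ph.start - 1, ph.start - 1 + ph.winsize)
        sty_in = [i for i in window if seq[i] in PHOSPHO_RESIDUES]
        deficit = ph.n_sites - len(sty_in)
        if deficit > 0:
            non_sty = [i for i in window if seq[i] not in PHOSPHO_RESIDUES]
            for i in rng.choice(non_sty, size=deficit, replace=False):
                seq[int(i)] = "S"

    # write gain/loss cassettes and collect the engineered SNP specs
    planted_specs: list[_PlantedSnpSpec] = []
    for idx, planted in enumerate(config.planted_gain_loss):
        seq = sequences[idx]
        center = len(seq) // 2  # 0-based
        if center - CASSETTE_HALF < 0 or center + CASSETTE_HALF >= len(seq):
            raise SimulationConfigError("protein too short for a planted cassette")
        layout, (sub_offset, ref_aa, alt_aa) = _CASSETTE_LAYOUT[
            (planted.kind, planted.status)
        ]
        for off in range(-CASSETTE_HALF, CASSETTE_HALF + 1):
            seq[center + off] = layout.get(off, "A")
        ref_codon, alt_codon, base_index = _single_base_change(ref_aa, alt_aa)
        ref_seq = "".join(seq)
        mut_seq = (
            ref_seq[: center + sub_offset]
            + alt_aa
            + ref_seq[center + sub_offset + 1 :]
        )
        _verify_cassette(planted, ref_seq, mut_seq, center + 1)
        planted_specs.append(
            _PlantedSnpSpec(
                protein_index=idx,
                aa_pos=center + sub_offset + 1,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                base_index=base_index,
                event={
                    "protein_id": _pid(idx),
                    "position": center + 1,
                    "kind": planted.kind,
                    "status": planted.status,
                },
            )
        )
    forced_codons = {
        (spec.protein_index, spec.aa_pos): spec.ref_codon for spec in planted_specs
    }

    # build CDS (synonymous codon sampling + stop), exons, genome
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_offsets = {name: 0 for name in chrom_parts}
    proteins: dict[str, ProteinRecord] = {}
    proteome: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    cds_by_gene: dict[str, str] = {}
    for i, seq in enumerate(sequences):
        pid = _pid(i)
        protein_seq = "".join(seq)
        codons = []
        for pos, aa in enumerate(protein_seq, start=1):
            forced = forced_codons.get((i, pos))
            codons.append(forced if forced else rng.choice(CODONS_OF[aa]))
        codons.append(STOP_CODONS[int(rng.integers(len(STOP_CODONS)))])
        cds = "".join(codons)

        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(1, config.max_exons + 1))
        genomic_exonic = cds if strand == "+" else revcomp(cds)
        cuts = (
            sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                              replace=False))
            if n_exons > 1
            else []
        )
        pieces = np.split(np.frombuffer(genomic_exonic.encode(), dtype=np.uint8),
                          cuts)
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        spacer_len = int(rng.integers(100, 300))
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
        chrom_parts[chrom].append(spacer)
        chrom_offsets[chrom] += spacer_len
        exons = []
        for j, piece in enumerate(pieces):
            exon_seq = piece.tobytes().decode()
            start = chrom_offsets[chrom] + 1
            end = start + len(exon_seq) - 1
            exons.append((start, end))
            chrom_parts[chrom].append(exon_seq)
            chrom_offsets[chrom] += len(exon_seq)
            if j < len(pieces) - 1:
                ilen = int(rng.integers(*config.intron_length))
                intron = "".join(rng.choice(list("ACGT"), size=ilen))
                chrom_parts[chrom].append(intron)
                chrom_offsets[chrom] += ilen
        proteins[pid] = ProteinRecord(id=pid, sequence=protein_seq, gene_id=pid)
        proteome[pid] = protein_seq
        models[pid] = GeneModel(
            gene_id=pid, chrom=chrom, strand=strand, exons=tuple(exons)
        )
        cds_by_gene[pid] = cds
    genome = {name: "".join(parts) for name, parts in chrom_parts.items()}

    # exclusion zone: no random SNPs inside planted cassette codons
    exclude: dict[str, set[int]] = {name: set() for name in genome}
    for spec in planted_specs:
        pid = _pid(spec.protein_index)
        model = models[pid]
        center_pos = spec.event["position"]
        for aa_pos in range(center_pos - CASSETTE_HALF,
                            center_pos + CASSETTE_HALF + 1):
            for k in range(3):
                cds_pos = 3 * (aa_pos - 1) + k + 1
                exclude[model.chrom].add(cds_to_genomic(model, cds_pos))

    data = SimulatedData(
        config=config,
        proteins=proteins,
        proteome=proteome,
        models=models,
        genome=genome,
        cds_by_gene=cds_by_gene,
    )
    data._planted_specs = planted_specs
    data._snp_exclude = exclude
    data.truth = {
        "planted_hotspots": [
            {
                "protein_id": _pid(ph.protein_index),
                "start": ph.start,
                "winsize": ph.winsize,
                "n_sites": ph.n_sites,
            }
            for ph in config.planted_hotspots
        ],
        "planted_gain_loss": [],
        "phospho_prob": dict(config.phospho_prob),
    }
    return data


def _pid(index: int) -> str:
    return f"P{index + 1:04d}"


def _verify_cassette(
    planted: PlantedGainLoss, ref_seq: str, mut_seq: str, center_pos: int
) -> None:
    """Check the planted cassette realises the requested score transition."""
    if planted.status == 2:
        seq = ref_seq if planted.kind == "loss" else mut_seq
        if toy_scorer(seq, center_pos) < 1.0:
            raise SimulationConfigError("cassette fails high-confidence check")
        return
    ref_score = toy_scorer(ref_seq, center_pos)
    alt_score = toy_scorer(mut_seq, center_pos)
    ok = (
        ref_score >= 1.0 and alt_score <= -1.0
        if planted.kind == "loss"
        else ref_score <= -1.0 and alt_score >= 1.0
    )
    if not ok:
        raise SimulationConfigError(
            f"cassette scores ({ref_score:.2f} -> {alt_score:.2f}) do not "
            f"realise a status-1 {planted.kind}"
        )


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------


def generate_sites(data: SimulatedData, config: SimulationConfig) -> list[PhosphoSite]:
    """Experimental phosphosites: independent Bernoulli draws per S/T/Y.

    Planted hotspots are forced to carry at least their requested number of
    sites inside the window (positions drawn among the window's S/T/Y).
    """
    rng = np.random.default_rng([config.seed, 1])
    sites: dict[tuple[str, int], PhosphoSite] = {}
    for pid, seq in data.proteome.items():
        for pos0, aa in enumerate(seq):
            if aa in PHOSPHO_RESIDUES and rng.random() < config.phospho_prob[aa]:
                sites[(pid, pos0 + 1)] = PhosphoSite(
                    pid, pos0 + 1, aa, "experimental"
                )
    for ph in config.planted_hotspots:
        pid = _pid(ph.protein_index)
        seq = data.proteome[pid]
        window_sty = [
            pos0 + 1
            for pos0 in range(ph.start - 1, ph.start - 1 + ph.winsize)
            if seq[pos0] in PHOSPHO_RESIDUES
        ]
        if len(window_sty) < ph.n_sites:
            raise SimulationConfigError(
                f"planted hotspot window in {pid} has only {len(window_sty)} "
                f"S/T/Y for {ph.n_sites} sites"
            )
        present = [p for p in window_sty if (pid, p) in sites]
        deficit = ph.n_sites - len(present)
        if deficit > 0:
            absent = [p for p in window_sty if (pid, p) not in sites]
            for pos in rng.choice(absent, size=deficit, replace=False):
                pos = int(pos)
                sites[(pid, pos)] = PhosphoSite(
                    pid, pos, seq[pos - 1], "experimental"
                )
    out = sorted(sites.values(), key=lambda s: (s.protein_id, s.position))
    data.sites_experimental = out
    return out


def predicted_scores(proteome: dict[str, str]) -> dict[str, dict[int, float]]:
    """Toy-scorer decision values for every S/T/Y position."""
    return {
        pid: {
            pos0 + 1: toy_scorer(seq, pos0 + 1)
            for pos0, aa in enumerate(seq)
            if aa in PHOSPHO_RESIDUES
        }
        for pid, seq in proteome.items()
    }


def generate_predicted_sites(data: SimulatedData) -> list[PhosphoSite]:
    """High-confidence predicted sites: S/T/Y with toy score >= 1."""
    scores = predicted_scores(data.proteome)
    sites = [
        PhosphoSite(pid, pos, data.proteome[pid][pos - 1], "predicted", score)
        for pid, per_pos in scores.items()
        for pos, score in per_pos.items()
        if score >= 1.0
    ]
    sites.sort(key=lambda s: (s.protein_id, s.position))
    data.predicted_scores = scores
    data.sites_predicted = sites
    return sites


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------


def generate_snps(
    data: SimulatedData,
    config: SimulationConfig,
    sites: list[PhosphoSite] | None = None,
) -> list[SnpRecord]:
    """SNPs at the configured per-coding-base rate plus planted events.

    Random SNPs hit coding and intronic bases alike; each is carried by
    every accession independently with the allele-sharing probability (at
    least one carrier is guaranteed).  Planted gain/loss SNPs are emitted
    with a single accession; an optional planted substitution bias places
    from->to substitutions more often at phosphosites than elsewhere.
    """
    rng = np.random.default_rng([config.seed, 2])
    accessions = [f"acc{i + 1:02d}" for i in range(config.n_accessions)]
    bases = np.array(list("ACGT"))
    snps: dict[tuple[str, int, str], SnpRecord] = {}

    def draw_accessions() -> frozenset[str]:
        mask = rng.random(config.n_accessions) < config.allele_sharing_prob
        chosen = [a for a, m in zip(accessions, mask) if m]
        if not chosen:
            chosen = [accessions[int(rng.integers(config.n_accessions))]]
        return frozenset(chosen)

    if config.snp_rate > 0:
        for pid, model in data.models.items():
            span = range(model.exons[0][0], model.exons[-1][1] + 1)
            gene_positions = np.array(span)
            hits = gene_positions[
                rng.random(len(gene_positions)) < config.snp_rate
            ]
            excluded = data._snp_exclude.get(model.chrom, set())
            for gpos in hits:
                gpos = int(gpos)
                if gpos in excluded:
                    continue
                ref = data.genome[model.chrom][gpos - 1]
                alt = str(rng.choice(bases[bases != ref]))
                key = (model.chrom, gpos, alt)
                if key not in snps:
                    snps[key] = SnpRecord(
                        model.chrom, gpos, ref, alt, draw_accessions()
                    )

    if config.planted_substitution is not None:
        _plant_substitution_bias(data, config, sites, rng, snps, draw_accessions)

    truth_events = []
    for i, spec in enumerate(data._planted_specs):
        pid = _pid(spec.protein_index)
        model = data.models[pid]
        cds_pos = 3 * (spec.aa_pos - 1) + spec.base_index + 1
        gpos = cds_to_genomic(model, cds_pos)
        ref_cds = spec.ref_codon[spec.base_index]
        alt_cds = spec.alt_codon[spec.base_index]
        if model.strand == "-":
            ref_g, alt_g = revcomp(ref_cds), revcomp(alt_cds)
        else:
            ref_g, alt_g = ref_cds, alt_cds
        accession = accessions[i % len(accessions)]
        key = (model.chrom, gpos, alt_g)
        snps[key] = SnpRecord(model.chrom, gpos, ref_g, alt_g,
                              frozenset([accession]))
        truth_events.append({**spec.event, "accession": accession})

    data.truth["planted_gain_loss"] = truth_events
    out = sorted(snps.values(), key=lambda s: (s.chrom, s.pos, s.alt))
    data.snps = out
    return out


def _plant_substitution_bias(data, config, sites, rng, snps, draw_accessions):
    planted = config.planted_substitution
    if sites is None:
        raise SimulationConfigError(
            "planted substitution bias requires the site set"
        )
    site_pos = {(s.protein_id, s.position) for s in sites}
    for pid, seq in data.proteome.items():
        model = data.models[pid]
        cds = data.cds_by_gene[pid]
        excluded = data._snp_exclude.get(model.chrom, set())
        for pos0, aa in enumerate(seq):
            if aa != planted.from_residue:
                continue
            pos = pos0 + 1
            rate = planted.base_rate * (
                planted.factor if (pid, pos) in site_pos else 1.0
            )
            if rng.random() >= rate:
                continue
            codon = cds[3 * pos0 : 3 * pos0 + 3]
            change = None
            for alt_codon in CODONS_OF[planted.to_residue]:
                diff = [k for k in range(3) if codon[k] != alt_codon[k]]
                if len(diff) == 1:
                    change = (alt_codon, diff[0])
                    break
            if change is None:  # this codon cannot reach the target in one step
                continue
            alt_codon, k = change
            cds_pos = 3 * pos0 + k + 1
            gpos = cds_to_genomic(model, cds_pos)
            if gpos in excluded:
                continue
            ref_cds, alt_cds = codon[k], alt_codon[k]
            if model.strand == "-":
                ref_g, alt_g = revcomp(ref_cds), revcomp(alt_cds)
            else:
                ref_g, alt_g = ref_cds, alt_cds
            key = (model.chrom, gpos, alt_g)
            if key not in snps:
                snps[key] = SnpRecord(model.chrom, gpos, ref_g, alt_g,
                                      draw_accessions())


# ---------------------------------------------------------------------------
# Domains and terms
# ---------------------------------------------------------------------------


def generate_domains_terms(
    data: SimulatedData, config: SimulationConfig
) -> tuple[list[DomainAnnotation], list[TermAnnotation]]:
    """Domains covering ~the configured residue fraction, plus term labels.

    Per protein, the number of domains is the probabilistically rounded
    coverage * length / mean domain length (so the expected covered fraction
    equals ``domain_coverage`` without end-effect bias); the uncovered
    residues are split into random gaps around them.  Terms are assigned per
    (protein, term) with the base rate; the optional enrichment triple
    (term_id, protein subset, factor) multiplies that rate within the
    subset.
    """
    rng = np.random.default_rng([config.seed, 3])
    domains: list[DomainAnnotation] = []
    lo, hi = config.domain_length
    mean_dom = (lo + hi) / 2.0
    cov = config.domain_coverage
    if cov > 0:
        for pid, seq in data.proteome.items():
            length = len(seq)
            x = cov * length / mean_dom
            k = int(x) + (rng.random() < (x - int(x)))
            if k == 0:
                continue
            dlens = rng.integers(lo, hi + 1, size=k)
            while dlens.sum() > 0.9 * length and k > 1:
                k -= 1
                dlens = dlens[:k]
            if dlens.sum() > 0.9 * length:
                dlens = np.array([max(5, int(0.9 * length))])
            remaining = length - int(dlens.sum())
            gaps = rng.multinomial(remaining, [1.0 / (k + 1)] * (k + 1))
            pos = 1
            for j, dlen in enumerate(dlens):
                pos += int(gaps[j])
                domains.append(
                    DomainAnnotation(pid, pos, pos + int(dlen) - 1,
                                     f"DOM{j + 1:02d}")
                )
                pos += int(dlen)
    terms: list[TermAnnotation] = []
    enriched_term, enriched_set, factor = (None, frozenset(), 1.0)
    if config.term_enrichment is not None:
        enriched_term, subset, factor = config.term_enrichment
        enriched_set = frozenset(subset)
    for pid in data.proteome:
        for t in range(config.n_terms):
            term_id = f"TERM{t + 1:03d}"
            rate = config.term_base_rate
            if term_id == enriched_term and pid in enriched_set:
                rate = min(1.0, rate * factor)
            if rng.random() < rate:
                terms.append(TermAnnotation(pid, term_id))
    data.domains = domains
    data.terms = terms
    return domains, terms


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimulatedData:
    """Run every generator in sequence and return the full dataset."""
    data = generate_proteome(config)
    generate_sites(data, config)
    generate_predicted_sites(data)
    generate_snps(data, config, sites=data.sites_predicted)
    generate_domains_terms(data, config)
    return data
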