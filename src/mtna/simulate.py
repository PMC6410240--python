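"""Synthetic inputs for every pipeline stage, with known ground truth.

The generators emulate the data the analyses were designed for:

* dual-allele references for a 49-bp presence/absence indel and short reads
  (45–150 bp, single or paired) drawn from an allele embedded in a longer
  genomic context, so only some reads span the junction — including mixed
  templates emulating residual polymorphism in pooled inbred lines;
* diploid genotype counts from a population at allele frequency ``p`` with
  Wright's inbreeding coefficient ``F``;
* qPCR Ct tables (target + reference gene, biological and technical
  replicates) with an additive genotype effect on the target Ct;
* per-line expression and stress-survival records with multiplicative
  hazard effects (exponential baseline, administrative censoring);
* a two-population alignment with within-population diversity, divergent
  outgroups, and "migrant" haplotypes copied from one population but
  labelled as the other — the admixture signal the tree analysis detects.

All randomness flows from explicit seeds; the same seed reproduces every
output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import DELETION, NON_DELETION, AlleleReference, encode_seq
from .io import phred_string
from .phylo import Alignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class QpcrParams:
    """Ct model: Ct = gene baseline − genotype effect (target only, deletion
    genotype) + biological noise, with technical noise per replicate well."""

    baseline_ct_target: float = 22.0
    baseline_ct_reference: float = 18.0
    # additive Ct decrease of the deletion genotype per genetic background;
    # log2(1.85) and log2(1.20) are the two-background study conditions
    genotype_effect: dict = field(
        default_factory=lambda: {
            "M12": math.log2(1.85),
            "M9": math.log2(1.20),
        }
    )
    bio_sd: float = 0.3
    tech_sd: float = 0.1
    n_biological: int = 25
    n_technical: int = 2


@dataclass
class SurvivalParams:
    """Exponential-baseline survival with multiplicative hazard ratios,
    plus per-line log2 expression values (two replicates per sex)."""

    n_lines: int = 150
    n_replicates: int = 5  # flies scored per line x sex x agent
    baseline_scale_hours: float = 48.0
    hazard_ratio_deletion: dict = field(
        default_factory=lambda: {"MSB": 0.6, "paraquat": 1.0}
    )
    hazard_ratio_male: float = 0.7
    censor_time_hours: float = 480.0
    expr_mean: float = 6.0
    expr_line_sd: float = 0.35
    expr_rep_sd: float = 0.15
    # log2 expression increase of deletion lines, per sex (folds 1.33/1.40)
    expr_effect: dict = field(
        default_factory=lambda: {
            "F": math.log2(1.33),
            "M": math.log2(1.40),
        }
    )
    expr_sex_effect: float = math.log2(1.67)  # male-biased expression


@dataclass
class AlignmentParams:
    n_per_population: int = 20
    length_bp: int = 15_000
    divergence: float = 0.05  # between-population founder divergence
    diversity: float = 0.005  # expected within-population pairwise distance
    n_migrants: int = 5
    n_outgroups: int = 2
    outgroup_divergence: float = 0.15
    population_a: str = "Zambia"
    population_b: str = "France"


@dataclass
class SimConfig:
    """Bundled generator parameters; one seed drives everything."""

    seed: int = 0
    read_length_range: tuple[int, int] = (150, 150)
    paired: bool = True
    coverage: float = 20.0  # mean junction-overlapping reads per line
    error_rate: float = 0.001  # per-base substitution probability
    p_del: float = 0.91
    inbreeding_f: float = 0.0
    context_length: int = 2000  # genomic context around the indel
    fragment_length: int = 300  # paired-end outer distance
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self):
        if not 0 <= self.p_del <= 1:
            raise ValueError("p_del must be in [0, 1]")
        if not -1 <= self.inbreeding_f <= 1:
            raise ValueError("inbreeding_f must be in [-1, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        lo, hi = self.read_length_range
        if not 1 <= lo <= hi:
            raise ValueError("read_length_range must be a positive ordered pair")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_references(
    upstream_flank: int = 49,
    downstream_flank: int = 41,
    indel_length: int = 49,
    context: str | None = None,
    seed: int | None = None,
) -> tuple[AlleleReference, AlleleReference]:
    """Build the deletion/non-deletion allele reference pair.

    ``context``, if given, is the full non-deletion sequence
    (upstream + indel + downstream); otherwise a uniform random sequence is
    generated. The deletion reference is the two flanks joined at the
    junction; the non-deletion reference carries ``indel_length`` extra
    bases between them.
    """
    if upstream_flank < 1 or downstream_flank < 1 or indel_length < 1:
        raise ValueError("flank and indel lengths must be >= 1")
    total = upstream_flank + indel_length + downstream_flank
    if context is None:
        context = _random_dna(np.random.default_rng(seed), total)
    context = context.upper()
    if len(context) != total:
        raise ValueError(f"context must be {total} bp (flanks + indel)")
    if set(context) - set("ACGT"):
        raise ValueError("context contains non-DNA characters")
    up = context[:upstream_flank]
    insert = context[upstream_flank : upstream_flank + indel_length]
    down = context[upstream_flank + indel_length :]
    deletion = AlleleReference(DELETION, up + down, junction=upstream_flank)
    non_deletion = AlleleReference(
        NON_DELETION,
        up + insert + down,
        interval=(upstream_flank, upstream_flank + indel_length),
    )
    return deletion, non_deletion


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    true_allele: str
    spans_junction: bool


def _apply_errors(codes: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape[0]) < error_rate
    n_err = int(mask.sum())
    if n_err:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_err)) % 4
    return codes


def _normalize_genotype(genotype) -> float:
    """Deletion-template probability for a line genotype spec."""
    if genotype == DELETION:
        return 1.0
    if genotype == NON_DELETION:
        return 0.0
    if isinstance(genotype, tuple) and genotype[0] == "mixed":
        genotype = genotype[1]
    try:
        f = float(genotype)
    except (TypeError, ValueError):
        raise ValueError(f"unknown genotype spec {genotype!r}") from None
    if not 0 <= f <= 1:
        raise ValueError("mixed fraction must be in [0, 1]")
    return f


def simulate_line_reads(
    genotype,
    refs: tuple[AlleleReference, AlleleReference],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    line_id: str = "line",
) -> list[SimulatedRead]:
    """Simulate one line's reads around the indel locus.

    ``genotype`` is ``"deletion"``, ``"non_deletion"``, or a deletion-allele
    fraction in [0, 1] (``("mixed", f)`` also accepted) emulating residual
    polymorphism in a pooled line: each read's template allele is drawn
    independently with that probability. The allele sequences are embedded
    in a shared random genomic context so that many reads do not span the
    junction; substitution errors are applied per base and reads come from
    either strand. Quality strings are constant.
    """
    f_del = _normalize_genotype(genotype)
    if rng is None:
        rng = config.rng()
    del_ref = next(r for r in refs if r.allele_id == DELETION)
    non_ref = next(r for r in refs if r.allele_id == NON_DELETION)

    extra = config.context_length - len(non_ref.sequence)
    left_len = max(extra // 2, 0)
    right_len = max(extra - left_len, 0)
    left = _random_dna(rng, left_len)
    right = _random_dna(rng, right_len)
    templates = {
        DELETION: (left + del_ref.sequence + right, left_len + del_ref.junction),
        NON_DELETION: (
            left + non_ref.sequence + right,
            left_len + non_ref.interval[0],
        ),
    }
    enc = {k: encode_seq(seq) for k, (seq, _) in templates.items()}

    lo, hi = config.read_length_range
    mean_len = (lo + hi) / 2
    L = config.context_length
    # expected junction-spanning reads per read ~ (len-1)/(L-len+1)
    n_reads = max(1, round(config.coverage * (L - mean_len + 1) / (mean_len - 1))) if mean_len > 1 else 1
    reads: list[SimulatedRead] = []

    def emit(template_allele: str, start: int, length: int, mate: str) -> None:
        seq_codes, junction = (
            enc[template_allele],
            templates[template_allele][1],
        )
        start = min(max(start, 0), len(seq_codes) - length)
        codes = _apply_errors(
            seq_codes[start : start + length], config.error_rate, rng
        )
        spans = start < junction < start + length
        if rng.random() < 0.5:
            rc = codes[::-1].copy()
            rc = (3 - rc) % 4
            codes = rc
        seq = bytes(_BASES[codes]).decode()
        reads.append(
            SimulatedRead(
                f"{line_id}:{len(reads)}{mate}",
                seq,
                phred_string(length),
                template_allele,
                spans,
            )
        )

    if config.paired:
        n_frags = max(1, (n_reads + 1) // 2)
        frag = max(config.fragment_length, hi)
        for _ in range(n_frags):
            allele = DELETION if rng.random() < f_del else NON_DELETION
            tmpl_len = len(enc[allele])
            fstart = int(rng.integers(0, max(tmpl_len - frag, 1)))
            l1 = int(rng.integers(lo, hi + 1))
            l2 = int(rng.integers(lo, hi + 1))
            emit(allele, fstart, l1, "/1")
            emit(allele, fstart + frag - l2, l2, "/2")
    else:
        for _ in range(n_reads):
            allele = DELETION if rng.random() < f_del else NON_DELETION
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(enc[allele]) - length + 1))
            emit(allele, start, length, "")
    return reads


def simulate_cohort_reads(
    n_lines: int,
    refs: tuple[AlleleReference, AlleleReference],
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, list[SimulatedRead]]]:
    """Haploid-line cohort: one true allele per line, reads per line.

    Returns ``(true_genotypes, reads_by_line)``.
    """
    rng = config.rng()
    truths: dict[str, str] = {}
    reads: dict[str, list[SimulatedRead]] = {}
    for i in range(n_lines):
        line_id = f"line{i:03d}"
        allele = DELETION if rng.random() < config.p_del else NON_DELETION
        truths[line_id] = allele
        reads[line_id] = simulate_line_reads(
            allele, refs, config, rng=rng, line_id=line_id
        )
    return truths, reads


def simulate_population(
    p_del: float,
    n_individuals: int,
    inbreeding_f: float = 0.0,
    seed: int | None = None,
    stratum: str = "simulated",
):
    """Multinomial genotype counts under allele frequency p and Wright's F.

    Genotype probabilities are (p² + Fpq, 2pq(1−F), q² + Fpq); an F that
    makes any of them negative for the given p is rejected.
    """
    from .popgen import GenotypeCounts

    if not 0 <= p_del <= 1:
        raise ValueError("p_del must be in [0, 1]")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    q = 1 - p_del
    probs = np.array(
        [
            p_del**2 + inbreeding_f * p_del * q,
            2 * p_del * q * (1 - inbreeding_f),
            q**2 + inbreeding_f * p_del * q,
        ]
    )
    if np.any(probs < -1e-12):
        raise ValueError(f"infeasible inbreeding F={inbreeding_f} for p={p_del}")
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_individuals, probs)
    return GenotypeCounts(*map(int, counts), stratum=stratum)


def simulate_qpcr(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ct table for each background x genotype x replicate combination.

    Per biological replicate, the reference-gene Ct is Normal(baseline_ref,
    bio_sd) and the target Ct is Normal(baseline_target − effect·[deletion],
    bio_sd); each technical replicate adds Normal(0, tech_sd) per gene.
    """
    q = config.qpcr
    if rng is None:
        rng = config.rng(salt=1)
    rows = []
    for background, effect in q.genotype_effect.items():
        for genotype in (DELETION, NON_DELETION):
            shift = effect if genotype == DELETION else 0.0
            for b in range(q.n_biological):
                bio_t = rng.normal(q.baseline_ct_target - shift, q.bio_sd)
                bio_r = rng.normal(q.baseline_ct_reference, q.bio_sd)
                for t in range(q.n_technical):
                    rows.append(
                        dict(
                            background=background,
                            genotype=genotype,
                            bio_rep=b,
                            tech_rep=t,
                            ct_target=bio_t + rng.normal(0, q.tech_sd),
                            ct_ref=bio_r + rng.normal(0, q.tech_sd),
                        )
                    )
    return pd.DataFrame(rows)


def simulate_survival(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-line expression and stress-survival panel (both sexes, two agents).

    Survival times are exponential with hazard
    ``(1/baseline_scale) · HR_del^[deletion] · HR_male^[male]`` and
    administrative censoring; expression is log2-scale with per-line and
    per-replicate noise and sex-specific genotype effects.
    """
    s = config.survival
    if rng is None:
        rng = config.rng(salt=2)
    rows = []
    for i in range(s.n_lines):
        line_id = f"DGRP{i:03d}"
        is_del = rng.random() < config.p_del
        genotype = DELETION if is_del else NON_DELETION
        line_base = rng.normal(0.0, s.expr_line_sd)
        for sex in ("F", "M"):
            mu = (
                s.expr_mean
                + line_base
                + (s.expr_sex_effect if sex == "M" else 0.0)
                + (s.expr_effect[sex] if is_del else 0.0)
            )
            rep1 = mu + rng.normal(0, s.expr_rep_sd)
            rep2 = mu + rng.normal(0, s.expr_rep_sd)
            for agent, hr_del in s.hazard_ratio_deletion.items():
                hazard = (
                    (1.0 / s.baseline_scale_hours)
                    * (hr_del if is_del else 1.0)
                    * (s.hazard_ratio_male if sex == "M" else 1.0)
                )
                for rep in range(s.n_replicates):
                    t = rng.exponential(1.0 / hazard)
                    event = t <= s.censor_time_hours
                    rows.append(
                        dict(
                            line_id=line_id,
                            genotype=genotype,
                            sex=sex,
                            agent=agent,
                            replicate=rep,
                            expression_rep1=rep1,
                            expression_rep2=rep2,
                            expression=(rep1 + rep2) / 2,
                            survival_time=min(t, s.censor_time_hours),
                            event=int(event),
                        )
                    )
    return pd.DataFrame(rows)


def _mutate(codes: np.ndarray, p: float, rng) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.shape[0]) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_admixed_alignment(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Alignment, pd.DataFrame]:
    """Two-population alignment with migrant haplotypes and outgroups.

    Population A descends from the ancestral sequence; population B's
    founder is the ancestral sequence mutated at the between-population
    divergence. Every haplotype adds within-population diversity
    (per-sequence substitution probability = diversity/2, so the expected
    within-population pairwise distance ≈ diversity). Migrants are drawn
    from the B founder but labelled as population A — the admixture signal.
    Outgroups diverge independently at ``outgroup_divergence``.

    Returns the alignment and a taxon table (taxon, population, migrant,
    outgroup, carries_deletion).
    """
    a = config.alignment
    if rng is None:
        rng = config.rng(salt=3)
    ancestral = rng.integers(0, 4, size=a.length_bp).astype(np.uint8)
    founder = {
        a.population_a: ancestral,
        a.population_b: _mutate(ancestral, a.divergence, rng),
    }
    per_seq = a.diversity / 2
    names, rows, seqs = [], [], []

    def add(name, pop_label, founder_codes, migrant=False, outgroup=False):
        names.append(name)
        seqs.append(_mutate(founder_codes, per_seq, rng))
        rows.append(
            dict(
                taxon=name,
                population=pop_label,
                migrant=migrant,
                outgroup=outgroup,
                carries_deletion=migrant,
            )
        )

    for i in range(a.n_per_population):
        add(f"{a.population_a}_{i:02d}", a.population_a, founder[a.population_a])
    for i in range(a.n_migrants):
        add(
            f"{a.population_a}_mig_{i:02d}",
            a.population_a,
            founder[a.population_b],
            migrant=True,
        )
    for i in range(a.n_per_population):
        add(f"{a.population_b}_{i:02d}", a.population_b, founder[a.population_b])
    for i in range(a.n_outgroups):
        names.append(f"outgroup_{i}")
        seqs.append(_mutate(ancestral, a.outgroup_divergence, rng))
        rows.append(
            dict(
                taxon=names[-1],
                population="outgroup",
                migrant=False,
                outgroup=True,
                carries_deletion=False,
            )
        )
    aln = Alignment(names, np.vstack(seqs))
    return aln, pd.DataFrame(rows)


def expected_pairwise_distance(m1: float, m2: float, shared: float = 0.0) -> float:
    """Expected p-distance of two sequences independently mutated from a
    common founder at per-site substitution probabilities m1 and m2, the
    founders themselves differing at probability ``shared``.

    A site differs if exactly one lineage substituted (to a random other
    base), both substituted discordantly, or the founders differed and the
    substitutions did not erase it; the closed form below follows from the
    uniform choice among the 3 alternative bases at each substitution.
    """
    def combine(p_diff: float, m: float) -> float:
        # one extra round of substitutions at rate m on one sequence
        return p_diff * (1 - m) + p_diff * m * (2 / 3) + (1 - p_diff) * m

    p = shared
    p = combine(p, m1)
    p = combine(p, m2)
    return p


__all__ = [
    "SimConfig",
    "QpcrParams",
    "SurvivalParams",
    "AlignmentParams",
    "SimulatedRead",
    "make_references",
    "simulate_line_reads",
    "simulate_cohort_reads",
    "simulate_population",
    "simulate_qpcr",
    "simulate_survival",
    "simulate_admixed_alignment",
    "expected_pairwise_distance",
]
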