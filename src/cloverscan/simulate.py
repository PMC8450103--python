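"""Virtual genomes, false-positive evaluation, and the fixture generator.

Virtual genomes are drawn from a fifth-order Markov chain trained on a
source genome, preserving its local base composition (hexamer statistics)
while destroying any real gene structure — the negative control for
measuring false-positive rates at a given bit-score floor.

The fixture generator builds everything the test-suite needs offline:
toy cloverleaf seed alignments for a panel of nuclear isotypes (including
the three CAU-anticodon classes and a 9/4-fold selenocysteine tRNA), the
22 vertebrate mitochondrial classes with a D-armless Ser(GCU), two
bulge-helix-bulge intron families, an implanted ~100 kb nuclear genome
with truth annotations (plain, intron-bearing, boundary-truncated and
anticodon-mutated genes), and a ~16.6 kb implanted mitochondrial genome.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .config import ScanConfig
from .formats import SeedAlignment, parse_pairs
from .mito import VERT_MITO_CLASSES, class_name
from .model import ProfileSCFG, mask_anticodons, sample, seq_to_codes, train_model
from .records import NucSequence, revcomp
from .scanner import scan_sequences

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Markov background model

@dataclass
class MarkovModel:
    order: int
    cond: np.ndarray        # (4^order, 4) conditional probabilities
    initial: np.ndarray     # (4^order,) context start distribution
    source_length: int

    def __post_init__(self) -> None:
        if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional distributions must sum to 1")


def train_markov(seqs: list, order: int = 5,
                 pseudocount: float = 1.0) -> MarkovModel:
    """Estimate (order+1)-mer conditionals; windows containing N are skipped."""
    if not seqs:
        raise ValueError("no training sequences")
    C = 4 ** order
    counts = np.zeros((C, 4))
    ctx_counts = np.zeros(C)
    total = 0
    for s in seqs:
        codes = seq_to_codes(s.residues).astype(np.int64)
        total += len(codes)
        L = len(codes)
        if L <= order:
            continue
        valid = codes < 4
        ctx = np.zeros(L - order, dtype=np.int64)
        ok = np.ones(L - order, dtype=bool)
        for t in range(order):
            ctx = ctx * 4 + codes[t:L - order + t]
            ok &= valid[t:L - order + t]
        nxt = codes[order:]
        ok &= valid[order:]
        np.add.at(counts, (ctx[ok], nxt[ok]), 1)
        np.add.at(ctx_counts, ctx[ok], 1)
    if total <= 4 ** (order + 1):
        import warnings
        warnings.warn("training sequence shorter than 4^(order+1); "
                      "conditionals are pseudocount-dominated")
    cond = (counts + pseudocount)
    cond /= cond.sum(axis=1, keepdims=True)
    initial = ctx_counts + pseudocount
    initial /= initial.sum()
    return MarkovModel(order=order, cond=cond, initial=initial,
                       source_length=total)


@njit(cache=True)
def _gen_kernel(cond_cum, init_cum, order, length, u):
    C = cond_cum.shape[0]
    out = np.empty(length, np.int8)
    ctx = np.searchsorted(init_cum, u[0])
    if ctx >= C:
        ctx = C - 1
    tmp = ctx
    for t in range(order - 1, -1, -1):
        out[t] = tmp % 4
        tmp //= 4
    for i in range(order, length):
        row = cond_cum[ctx]
        r = u[i]
        x = 0
        while x < 3 and r > row[x]:
            x += 1
        out[i] = x
        ctx = (ctx * 4 + x) % C
    return out


def generate_virtual_genome(m: MarkovModel, length: int, rng_seed,
                            seq_id: str = "virtual") -> NucSequence:
    """Deterministically sample a virtual genome from a Markov model."""
    if length <= m.order:
        raise ValueError("length must exceed the Markov order")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    u = rng.random(length)
    codes = _gen_kernel(np.cumsum(m.cond, axis=1), np.cumsum(m.initial),
                        m.order, length, u)
    bases = np.array(list("ACGT"))
    return NucSequence(seq_id, "".join(bases[codes]))


def fp_evaluate(models, genomes: list, score_floor: float = 10.0,
                scan_cfg: ScanConfig = None):
    """Scan virtual genomes; tally hits into 1-bit score bins.

    Returns ``(histogram DataFrame, max_score, total_hits)``.
    """
    base = scan_cfg or ScanConfig()
    cfg = ScanConfig(
        first_pass_cutoff=min(base.first_pass_cutoff, score_floor),
        report_cutoff=score_floor,
        candidate_flank=base.candidate_flank,
        max_mode_window=base.max_mode_window,
        max_mode_overlap=base.max_mode_overlap,
    )
    if isinstance(models, ProfileSCFG):
        models = [models]
    scores = []
    for model in models:
        for g in genomes:
            for h in scan_sequences(model, [g], cfg):
                scores.append(h.score)
    bins = {}
    for s in scores:
        b = int(np.floor(s))
        bins[b] = bins.get(b, 0) + 1
    hist = pd.DataFrame(
        [(b, b + 1, n) for b, n in sorted(bins.items())],
        columns=["bin_low", "bin_high", "count"],
    )
    max_score = max(scores) if scores else float("nan")
    return hist, max_score, len(scores)


# ---------------------------------------------------------------------------
# Toy tRNA family construction

def cloverleaf_template(fold: str = "standard"):
    """(ss_cons, anticodon columns) for each supported architecture."""
    if fold == "standard":
        # 76-column cloverleaf; mature genes stay comfortably above the
        # 70-nt archaeal minimum even with a few sampled deletions
        ss = ("(" * 7 + "." + "(" * 4 + "." * 8 + ")" * 4 + "."
              + "(" * 5 + "." * 7 + ")" * 5 + "." * 9
              + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + ".")
        ac = 7 + 1 + 4 + 8 + 4 + 1 + 5 + 2
    elif fold == "d_armless":
        ss = ("(" * 7 + "." + "." * 5
              + "(" * 5 + "." * 7 + ")" * 5 + "." * 4
              + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + ".")
        ac = 7 + 1 + 5 + 5 + 2
    elif fold == "sec_9_4":
        ss = ("(" * 9 + "." + "(" * 4 + "." * 6 + ")" * 4 + "."
              + "(" * 6 + "." * 7 + ")" * 6 + "." * 4
              + "(" * 4 + "." * 7 + ")" * 4 + ")" * 9 + ".")
        ac = 9 + 1 + 4 + 6 + 4 + 1 + 6 + 2
    elif fold == "sec_8_5":
        ss = ("(" * 8 + "." + "(" * 4 + "." * 6 + ")" * 4 + "."
              + "(" * 6 + "." * 7 + ")" * 6 + "." * 4
              + "(" * 5 + "." * 7 + ")" * 5 + ")" * 8 + ".")
        ac = 8 + 1 + 4 + 6 + 4 + 1 + 6 + 2
    else:
        raise ValueError(f"unknown fold {fold!r}")
    return ss, (ac, ac + 1, ac + 2)


def random_consensus(rng, ss: str) -> list:
    """A random structure-compatible consensus for a template."""
    pairs = parse_pairs(ss)
    bases = "ACGT"
    cons = [""] * len(ss)
    for c in range(len(ss)):
        if c in pairs and pairs[c] > c:
            l = bases[rng.integers(4)]
            cons[c], cons[pairs[c]] = l, _COMP[l]
        elif c not in pairs:
            cons[c] = bases[rng.integers(4)]
    return cons


def derive_consensus(rng, master: list, ss: str, diverge: float) -> list:
    """Mutate a fraction of columns (stems compensatorily) off a master.

    Families within a domain share most of their consensus, as real tRNAs
    do; the diverged columns are what isotype-specific models key on.
    """
    pairs = parse_pairs(ss)
    bases = "ACGT"
    cons = list(master)
    for c in range(len(ss)):
        if c in pairs:
            if pairs[c] > c and rng.random() < diverge:
                l = bases[rng.integers(4)]
                cons[c], cons[pairs[c]] = l, _COMP[l]
        elif rng.random() < diverge:
            cons[c] = bases[rng.integers(4)]
    return cons


def build_family_alignment(rng, isotype: str, anticodon: str,
                           domain: str = "eukaryote",
                           fold: str = "standard", nrows: int = 400,
                           mut: float = 0.08, gap_rate: float = 0.02,
                           name: str = None,
                           consensus: list = None) -> SeedAlignment:
    """A toy family: fixed consensus, compensatory stem variation.

    The anticodon columns are invariant across rows, as in real
    isotype/anticodon families; loops mutate independently and stems
    mutate as compensated complementary pairs, giving the covariation
    signal that structural scoring exploits.
    """
    ss, ac_cols = cloverleaf_template(fold)
    pairs = parse_pairs(ss)
    width = len(ss)
    bases = "ACGT"
    cons = list(consensus) if consensus is not None else random_consensus(rng, ss)
    for k, c in enumerate(ac_cols):
        cons[c] = anticodon[k]

    rows = []
    for r in range(nrows):
        row = list(cons)
        for c in range(width):
            if c in ac_cols:
                continue
            if c in pairs:
                if pairs[c] > c and rng.random() < mut:
                    l = bases[rng.integers(4)]
                    row[c], row[pairs[c]] = l, _COMP[l]
            else:
                if rng.random() < mut:
                    row[c] = bases[rng.integers(4)]
                if rng.random() < gap_rate:
                    row[c] = "-"
        rows.append((f"{isotype}{anticodon}_{r}", "".join(row)))
    return SeedAlignment(
        rows=rows, ss_cons=ss, anticodon_cols=ac_cols,
        name=name or f"{isotype}-{anticodon}", domain=domain,
        isotype=isotype, fold=fold,
    )


def build_bhb_alignment(rng, name: str, nrows: int = 150,
                        mut: float = 0.06) -> SeedAlignment:
    """A toy bulge-helix-bulge intron family (~26 nt)."""
    ss = ".." + "(" * 6 + "." * 8 + ")" * 6 + "...."
    pairs = parse_pairs(ss)
    width = len(ss)
    bases = "ACGT"
    cons = [""] * width
    for c in range(width):
        if c in pairs and pairs[c] > c:
            l = bases[rng.integers(4)]
            cons[c], cons[pairs[c]] = l, _COMP[l]
        elif c not in pairs:
            cons[c] = bases[rng.integers(4)]
    rows = []
    for r in range(nrows):
        row = list(cons)
        for c in range(width):
            if c in pairs:
                if pairs[c] > c and rng.random() < mut:
                    l = bases[rng.integers(4)]
                    row[c], row[pairs[c]] = l, _COMP[l]
            elif rng.random() < mut:
                row[c] = bases[rng.integers(4)]
        rows.append((f"{name}_{r}", "".join(row)))
    return SeedAlignment(rows=rows, ss_cons=ss, anticodon_cols=None,
                         name=name, domain="archaea", isotype="intron",
                         fold="standard")


# ---------------------------------------------------------------------------
# Fixture set

NUCLEAR_FAMILIES = (
    ("Ala", "TGC", "standard"), ("Gly", "GCC", "standard"),
    ("Leu", "CAA", "standard"), ("Tyr", "GTA", "standard"),
    ("iMet", "CAT", "standard"), ("Met", "CAT", "standard"),
    ("Ile2", "CAT", "standard"), ("SeC", "TCA", "sec_9_4"),
)
STANDARD_FAMILY_NAMES = tuple(
    f"{i}-{a}" for i, a, f in NUCLEAR_FAMILIES if f == "standard"
)


@dataclass
class TruthRecord:
    seq_id: str
    begin: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    kind: str = "plain"     # plain | canonical_intron | bhb | trunc | ipd
    introns: list = field(default_factory=list)   # genomic (begin, end)


@dataclass
class FixtureSet:
    seed: int
    nuclear_alignments: dict
    bhb_alignments: dict
    mito_alignments: dict
    family_models: dict          # per-family (unmasked) nuclear models
    domain_model: ProfileSCFG    # anticodon-masked merged scan model
    bhb_models: dict
    genome: NucSequence
    truth: list
    mito_genome: NucSequence
    mito_truth: list

    def truth_bed(self, mito: bool = False) -> str:
        recs = self.mito_truth if mito else self.truth
        lines = [
            "\t".join([r.seq_id, str(r.begin), str(r.end),
                       f"{r.isotype}-{r.anticodon}", "0", r.strand])
            for r in recs
        ]
        return "\n".join(lines) + "\n"


def _sample_clean(model: ProfileSCFG, rng, max_tries: int = 50):
    """Sample until every anticodon column is emitted with the family base."""
    for _ in range(max_tries):
        s = sample(model, rng)
        if model.anticodon_cols is None:
            return s
        if s.anticodon(model) == model.anticodon:
            return s
    return s


def _sample_gene(model: ProfileSCFG, rng):
    """A clean sample trimmed to its consensus-emission span.

    Terminal insert runs (root-slot residues outside the outermost emitted
    consensus columns) are not part of the gene proper and are dropped;
    column positions are shifted accordingly.
    """
    s = _sample_clean(model, rng)
    pos = [p for p in s.col_positions.values()]
    b, e = min(pos), max(pos) + 1
    return (s.residues[b:e],
            {c: p - b for c, p in s.col_positions.items()})


def _sample_compact(model: ProfileSCFG, rng, slack: int = 10,
                    max_tries: int = 50) -> str:
    """A sampled member without atypically long insert runs.

    Implanted introns must present a formed, compact motif, so draws whose
    length exceeds the consensus span by more than ``slack`` are redrawn.
    """
    res, _ = _sample_gene(model, rng)
    for _ in range(max_tries):
        if len(res) <= model.ncols + slack:
            return res
        res, _ = _sample_gene(model, rng)
    return res


def make_fixture_set(rng_seed: int = 1, genome_length: int = 100_000,
                     n_plain: int = 42, nuclear_rows: int = 400,
                     mito_rows: int = 150) -> FixtureSet:
    """Build the full offline fixture set, deterministic per seed."""
    rng = np.random.default_rng(rng_seed)

    nuclear = {}
    family_models = {}
    masters = {}
    for isotype, anticodon, fold in NUCLEAR_FAMILIES:
        ss, _ = cloverleaf_template(fold)
        if fold not in masters:
            masters[fold] = random_consensus(rng, ss)
        cons = derive_consensus(rng, masters[fold], ss, diverge=0.18)
        aln = build_family_alignment(rng, isotype, anticodon, fold=fold,
                                     nrows=nuclear_rows, consensus=cons)
        nuclear[aln.name] = aln
        family_models[aln.name] = train_model(aln, name=aln.name)

    # merged, anticodon-masked scan model over the standard-fold families
    merged_rows = []
    base = nuclear[STANDARD_FAMILY_NAMES[0]]
    for name in STANDARD_FAMILY_NAMES:
        masked = mask_anticodons(nuclear[name])
        merged_rows.extend(masked.rows)
    merged = SeedAlignment(rows=merged_rows, ss_cons=base.ss_cons,
                           anticodon_cols=base.anticodon_cols,
                           name="general", domain="eukaryote", isotype="",
                           fold="standard")
    domain_model = train_model(merged, name="general")

    bhb = {}
    bhb_models = {}
    for name in ("bhb_cren", "bhb_thaum"):
        aln = build_bhb_alignment(rng, name)
        bhb[name] = aln
        # motif models stay compact: strict (Laplace) insert-run prior
        bhb_models[name] = train_model(aln, name=name, ext_prior=1.0)

    mito_alns = {}
    mito_masters = {}
    for isotype, anticodon, fold in VERT_MITO_CLASSES:
        name = class_name(isotype, anticodon)
        ss, _ = cloverleaf_template(fold)
        if fold not in mito_masters:
            mito_masters[fold] = random_consensus(rng, ss)
        cons = derive_consensus(rng, mito_masters[fold], ss, diverge=0.22)
        aln = build_family_alignment(rng, isotype, anticodon, domain="mito",
                                     fold=fold, nrows=mito_rows,
                                     name=name, consensus=cons)
        mito_alns[name] = aln

    # ---- nuclear implant genome -------------------------------------------
    source = generate_virtual_genome(
        train_markov([NucSequence(
            "src", "".join(np.array(list("ACGT"))[
                rng.choice(4, size=120_000, p=[0.3, 0.2, 0.2, 0.3])]))],
            order=5),
        120_000, rng, seq_id="markov_source")
    background_model = train_markov([source], order=5)
    genome_res = list(
        generate_virtual_genome(background_model, genome_length, rng,
                                seq_id="chrF").residues)

    implants = []   # (kind, family_name, payload)
    implants += [("trunc5", None), ("trunc3", None)]
    implants += [("canonical", None)] * 5
    implants += [("bhb1", None)] * 3
    implants += [("bhb2", None)]
    implants += [("ipd", None)] * 3
    implants += [("plain", None)] * n_plain

    n_impl = len(implants)
    gap = (genome_length - 400) // n_impl
    positions = [200 + k * gap + int(rng.integers(0, max(1, gap - 250)))
                 for k in range(n_impl)]

    truth = []
    euk_map_families = [n for n in STANDARD_FAMILY_NAMES]
    for k, (kind, _) in enumerate(implants):
        fam = euk_map_families[int(rng.integers(len(euk_map_families)))]
        model = family_models[fam]
        isotype, anticodon = fam.split("-")
        res, colpos = _sample_gene(model, rng)
        introns_rel = []
        if kind == "canonical":
            c37 = model.anticodon_cols[2] + 1
            while c37 not in colpos:
                res, colpos = _sample_gene(model, rng)
            ilen = int(rng.integers(13, 18))
            intron = generate_virtual_genome(background_model, ilen, rng,
                                             "i").residues
            at = colpos[c37] + 1
            res = res[:at] + intron + res[at:]
            introns_rel.append((at, at + ilen, "canonical"))
        elif kind in ("bhb1", "bhb2"):
            bhb_model = bhb_models["bhb_cren" if kind == "bhb1"
                                   else "bhb_thaum"]
            intron2 = _sample_compact(bhb_model, rng)
            at = colpos.get(model.anticodon_cols[2] + 2, len(res) // 2)
            res = res[:at] + intron2 + res[at:]
            introns_rel.append((at, at + len(intron2), "bhb"))
            if kind == "bhb2":
                intron1 = _sample_compact(bhb_models["bhb_cren"], rng)
                mid = at + len(intron2) // 2
                res = res[:mid] + intron1 + res[mid:]
                introns_rel = [(at, at + len(intron1) + len(intron2), "bhb"),
                               (mid, mid + len(intron1), "bhb")]
        elif kind == "ipd":
            # body of one family, anticodon of another: Leu body, Phe loop
            fam = "Leu-CAA"
            model = family_models[fam]
            res, colpos = _sample_gene(model, rng)
            res = list(res)
            for cc, b in zip(model.anticodon_cols, "GAA"):
                res[colpos[cc]] = b
            res = "".join(res)
            isotype, anticodon = "Phe", "GAA"
        elif kind == "trunc5":
            res = res[10:]
        elif kind == "trunc3":
            res = res[:-10]

        if kind == "trunc5":
            strand, pos = "+", 0
        elif kind == "trunc3":
            strand, pos = "+", genome_length - len(res)
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            pos = positions[k]
        ins = res if strand == "+" else revcomp(res)
        genome_res[pos:pos + len(res)] = list(ins)

        g_introns = []
        for b, e, ikind in introns_rel:
            if strand == "+":
                g_introns.append((pos + b, pos + e))
            else:
                g_introns.append((pos + len(res) - e, pos + len(res) - b))
        truth.append(TruthRecord(
            seq_id="chrF", begin=pos, end=pos + len(res), strand=strand,
            isotype=isotype, anticodon=anticodon, kind=kind,
            introns=sorted(g_introns)))

    genome = NucSequence("chrF", "".join(genome_res))

    # ---- mitochondrial implant genome -------------------------------------
    mito_len = 16_600
    mito_res = list(
        generate_virtual_genome(background_model, mito_len, rng,
                                "chrM").residues)
    mito_truth = []
    mgap = (mito_len - 400) // len(VERT_MITO_CLASSES)
    mito_models_tmp = {
        name: train_model(aln, name=name) for name, aln in mito_alns.items()
    }
    for k, (isotype, anticodon, fold) in enumerate(VERT_MITO_CLASSES):
        name = class_name(isotype, anticodon)
        res, _ = _sample_gene(mito_models_tmp[name], rng)
        pos = 200 + k * mgap + int(rng.integers(0, max(1, mgap - 150)))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = res if strand == "+" else revcomp(res)
        mito_res[pos:pos + len(res)] = list(ins)
        mito_truth.append(TruthRecord(
            seq_id="chrM", begin=pos, end=pos + len(res), strand=strand,
            isotype=isotype, anticodon=anticodon, kind="mito"))
    mito_genome = NucSequence("chrM", "".join(mito_res))

    return FixtureSet(
        seed=rng_seed, nuclear_alignments=nuclear, bhb_alignments=bhb,
        mito_alignments=mito_alns, family_models=family_models,
        domain_model=domain_model, bhb_models=bhb_models,
        genome=genome, truth=sorted(truth, key=lambda r: r.begin),
        mito_genome=mito_genome,
        mito_truth=sorted(mito_truth, key=lambda r: r.begin),
    )


def make_fp_background(rng_seed: int, length: int,
                       seq_id: str = "fp_background") -> NucSequence:
    """A pure Markov background genome with no implants (FP testing)."""
    rng = np.random.default_rng(rng_seed)
    src = NucSequence(
        "src", "".join(np.array(list("ACGT"))[
            rng.choice(4, size=200_000, p=[0.3, 0.2, 0.2, 0.3])]))
    m = train_markov([src], order=5)
    return generate_virtual_genome(m, length, rng, seq_id=seq_id)
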