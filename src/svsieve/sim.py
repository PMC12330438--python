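"""Synthetic-cohort generator with a complete ground-truth ledger.

Emulates the data structure the analysis assumes: a control panel of
deeply characterised genomes with a Beta-distributed SV allele-frequency
spectrum and a bimodal size distribution (Alu-like mode near 300 bp,
LINE-like mode near 6 kbp, log-normal background); simplex families (trios
and quads) whose genotypes follow Mendelian transmission; planted de novo,
private-inherited and biparental-homozygous events; sex chromosomes with
male hemizygosity outside the pseudoautosomal regions; and per-caller
callsets with breakpoint jitter, sequence divergence, imperfect
sensitivity and genotype error.

Every emitted call id embeds the id of the true locus it represents
(``<truth_id>@<sample>@<caller>``), so every record in every callset is
ledger-traceable.  Truth class labels (de novo / private inherited /
biparental homozygous / rare other) are derived from the realised true
genotypes by the same definitions the pipeline applies, which makes the
ledger an independent oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from svsieve.io import PafRecord
from svsieve.merge import GenotypeMatrix
from svsieve.types import (
    ALIGNER_A,
    ALIGNER_B,
    ASSEMBLY,
    ExclusionMask,
    Genotype,
    MergeParams,
    Pedigree,
    PedigreeEntry,
    SVRecord,
    is_sex_chrom,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FamilySpec:
    """One family: the first child is the affected proband, any further
    children are unaffected siblings."""

    structure: str = "quad"  # trio | quad
    child_sexes: tuple = ("female", "male")

    def __post_init__(self):
        n = {"trio": 1, "quad": 2}.get(self.structure)
        if n is None:
            raise ValueError(f"bad family structure {self.structure!r}")
        if len(self.child_sexes) != n:
            raise ValueError("child_sexes length must match structure")


DEFAULT_FAMILIES = (
    FamilySpec("quad", ("female", "male")),
    FamilySpec("quad", ("female", "female")),
    FamilySpec("quad", ("male", "male")),
    FamilySpec("quad", ("male", "female")),
    FamilySpec("trio", ("female",)),
    FamilySpec("trio", ("male",)),
)


def _default_contigs() -> dict:
    return {
        "chr1": 30_000_000,
        "chr2": 25_000_000,
        "chr3": 20_000_000,
        "chrX": 20_000_000,
        "chrY": 8_000_000,
    }


def _default_par() -> dict:
    return {"chrX": [(0, 1_000_000)], "chrY": [(0, 1_000_000)]}


def _default_sensitivity() -> dict:
    return {ASSEMBLY: 1.0, ALIGNER_A: 0.9, ALIGNER_B: 0.9}


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: dict = field(default_factory=_default_contigs)
    par: dict = field(default_factory=_default_par)
    n_controls: int = 100
    afr_fraction: float = 0.3
    families: tuple = DEFAULT_FAMILIES
    n_common_sv: int = 5000
    af_beta: tuple = (0.15, 8.0)
    afr_af_boost: float = 2.0
    size_weights: tuple = (0.5, 0.1, 0.4)
    size_alu: tuple = (300.0, 50.0)  # Alu-like mode (mean, sd)
    size_line: tuple = (6000.0, 800.0)  # LINE-like mode (mean, sd)
    size_lognorm: tuple = (5.0, 1.0)  # log-normal background (mu, sigma)
    ins_fraction: float = 0.5
    frac_x: float = 0.08
    frac_y: float = 0.02
    n_denovo_per_child: int = 2
    n_private_inherited: int = 3  # autosomal, per child
    plant_x_private: bool = True  # + one chrX private-inherited per child
    plant_y_private: bool = True  # + one chrY private per male child
    plant_x_hom: bool = True  # + one chrX homozygous (biparental) per female child
    n_biparental_hom: int = 1  # autosomal, per family
    breakpoint_jitter_sd: float = 30.0
    seq_divergence: float = 0.01
    genotype_error_rate: float = 0.02
    caller_sensitivity: dict = field(default_factory=_default_sensitivity)
    lambda_carrier: float = 10.0
    lambda_noise: float = 0.0
    tr_fraction: float = 0.1
    spacing: int = 4000  # minimum inter-locus slot width
    params: MergeParams = field(default_factory=MergeParams)

    def __post_init__(self):
        for rate in (self.afr_fraction, self.seq_divergence,
                     self.genotype_error_rate, self.tr_fraction, self.ins_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        trunc = self._jitter_trunc()
        if self.breakpoint_jitter_sd >= trunc + 1:
            raise ValueError(
                f"breakpoint_jitter_sd {self.breakpoint_jitter_sd} too large for "
                f"refdist {self.params.refdist}: planted identity would not survive merging"
            )

    def _jitter_trunc(self) -> int:
        # any two jittered representations of one locus stay within refdist
        return max(0, (self.params.refdist - 2) // 2)

    def mask(self) -> ExclusionMask:
        # PARs are both excluded from SV analysis and drive the ploidy lookup
        return ExclusionMask(intervals=self.par, par=self.par)


# ---------------------------------------------------------------------------
# low-level draws

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate_seq(rng: np.random.Generator, seq: str, rate: float, cap_frac: float) -> str:
    """Substitute bases at ``rate``, but never more than ``cap_frac`` of
    the length (keeps true pairs above the sequence-identity threshold)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(arr.size) < rate)
    cap = int(cap_frac * arr.size)
    if idx.size > cap:
        idx = idx[:cap]
    if idx.size:
        base_idx = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_idx + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes().decode()


def _sample_sizes(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(cfg.size_weights) / sum(cfg.size_weights))
    sizes = np.empty(n)
    for i, (mu, sd) in enumerate((cfg.size_alu, cfg.size_line)):
        m = comp == i
        sizes[m] = rng.normal(mu, sd, size=m.sum())
    m = comp == 2
    sizes[m] = rng.lognormal(cfg.size_lognorm[0], cfg.size_lognorm[1], size=m.sum())
    return np.clip(np.round(sizes), 50, cfg.params.sizemax).astype(int)


class _LocusPlacer:
    """Deterministic supply of well-separated positions per chromosome.

    Chromosomes are cut into fixed-width slots (PAR slots discarded on the
    sex chromosomes); slots are consumed in a shuffled order so any two
    issued loci are at least ~3/4 of a slot apart -- far beyond refdist,
    so distinct loci can never be merged."""

    def __init__(self, rng: np.random.Generator, cfg: SimulationConfig):
        self.rng = rng
        self.spacing = cfg.spacing
        self.slots: dict[str, list[int]] = {}
        mask = cfg.mask()
        for chrom, length in cfg.contigs.items():
            starts = []
            for s in range(0, length - cfg.spacing, cfg.spacing):
                mid = s + cfg.spacing // 2
                if (mask.in_par(chrom, s + 1) or mask.in_par(chrom, mid + 1)
                        or mask.in_par(chrom, s + cfg.spacing)):
                    continue
                starts.append(s)
            order = rng.permutation(len(starts))
            self.slots[chrom] = [starts[i] for i in order]

    def take(self, chrom: str) -> int:
        if not self.slots.get(chrom):
            raise ValueError(f"locus capacity exhausted on {chrom}")
        start = self.slots[chrom].pop()
        return int(start + self.rng.integers(1, self.spacing // 4))


def _draw_locus(
    rng: np.random.Generator, placer: _LocusPlacer, cfg: SimulationConfig,
    chrom: str, sv_id: str, size: Optional[int] = None,
) -> SVRecord:
    pos = placer.take(chrom)
    svlen = int(size if size is not None else _sample_sizes(rng, 1, cfg)[0])
    svtype = "INS" if rng.random() < cfg.ins_fraction else "DEL"
    seq = _random_seq(rng, svlen) if svtype == "INS" else None
    return SVRecord(id=sv_id, chrom=chrom, pos=pos, svtype=svtype, svlen=svlen,
                    qual=float(np.round(rng.uniform(30, 60), 1)), seq=seq)


def _hw_genotype(rng: np.random.Generator, af: float, chrom: str, sex: str) -> Optional[Genotype]:
    """Hardy-Weinberg draw, sex-aware; None for a female at a chrY locus."""
    c = chrom.replace("chr", "")
    if c == "Y":
        if sex == "female":
            return None
        return Genotype((int(rng.random() < af),))
    if c == "X" and sex == "male":
        return Genotype((int(rng.random() < af),))
    a1, a2 = int(rng.random() < af), int(rng.random() < af)
    return Genotype((a1, a2))


def _transmit(rng: np.random.Generator, fgt: Optional[Genotype], mgt: Optional[Genotype],
              chrom: str, child_sex: str) -> Optional[Genotype]:
    c = chrom.replace("chr", "")
    def pick(gt: Genotype) -> int:
        return int(gt.alleles[rng.integers(0, len(gt.alleles))])
    if c == "Y":
        if child_sex == "female":
            return None
        return Genotype((pick(fgt),))
    if c == "X":
        if child_sex == "male":
            return Genotype((pick(mgt),))
        return Genotype((pick(fgt), pick(mgt)))
    return Genotype((pick(fgt), pick(mgt)))


# ---------------------------------------------------------------------------
# cohort container

@dataclass
class Cohort:
    config: SimulationConfig
    panel: GenotypeMatrix  # control loci x control samples (alt carriers only)
    control_sexes: dict[str, str]
    control_superpops: dict[str, str]
    pedigree: Pedigree
    truth_records: dict[str, SVRecord]  # truth id -> locus
    truth_genotypes: dict[str, dict[str, Genotype]]  # truth id -> sample -> true gt
    ledger: pd.DataFrame  # one row per true locus
    callsets: dict[str, dict[str, list[SVRecord]]]  # sample -> caller -> calls
    call_genotypes: dict[str, dict[str, Genotype]]  # call id -> {sample: emitted gt}
    genotype_errors: list[tuple[str, str]]  # (sample, truth id) flipped at emission

    def truth_id_of(self, call_or_locus_id: str) -> str:
        return call_or_locus_id.split("@")[0]

    def family_samples(self) -> list[str]:
        return self.pedigree.samples

    def raw_parent_callsets(self, family_id: str) -> dict[str, list[SVRecord]]:
        out = {}
        for e in self.pedigree.family_members(family_id):
            if e.role in ("father", "mother"):
                calls: list[SVRecord] = []
                for caller_calls in self.callsets[e.sample_id].values():
                    calls.extend(caller_calls)
                out[e.sample_id] = calls
        return out

    # -- truth-side oracle ---------------------------------------------------

    def control_carriers(self, truth_id: str, sex: Optional[str] = None) -> list[str]:
        carriers = []
        for s in self.panel.samples:
            gt = self.truth_genotypes.get(truth_id, {}).get(s)
            if gt is not None and gt.has_alt:
                if sex is None or self.control_sexes[s] == sex:
                    carriers.append(s)
        return carriers

    def truth_rare_classes(self) -> pd.DataFrame:
        """Ground-truth rare (child, locus) table with category/class/origin.

        Applies the analysis definitions directly to the true genotypes:
        rare = child carries and no (sex-matched on X/Y) control carries;
        classes follow the de novo / private-inherited / biparental-
        homozygous definitions, else rare_other.
        """
        from svsieve.rarefilter import classify_category

        parents = {e.sample_id for e in self.pedigree.parents}
        rows = []
        for tid, rec in self.truth_records.items():
            gts = self.truth_genotypes.get(tid, {})
            parent_carriers = [s for s in parents if (g := gts.get(s)) is not None and g.has_alt]
            control_hom = any(
                (g := gts.get(s)) is not None and g.is_hom_alt for s in self.panel.samples
            )
            for child in self.pedigree.children:
                cgt = gts.get(child.sample_id)
                if cgt is None or not cgt.has_alt:
                    continue
                sex_filter = child.sex if is_sex_chrom(rec.chrom) else None
                if self.control_carriers(tid, sex_filter):
                    continue  # common: filtered by the panel
                fa, mo = self.pedigree.parents_of(child.sample_id)
                fgt, mgt = gts.get(fa), gts.get(mo)
                fa_c = fgt is not None and fgt.has_alt
                mo_c = mgt is not None and mgt.has_alt
                if not fa_c and not mo_c:
                    cls, origin = "de_novo", "none"
                elif (
                    not is_sex_chrom(rec.chrom)
                    and cgt.is_hom_alt and fgt.is_het and mgt.is_het
                    and not control_hom
                ):
                    cls, origin = "biparental_hom", "both"
                elif len(parent_carriers) == 1 and parent_carriers[0] in (fa, mo):
                    cls = "private_inherited"
                    origin = "paternal" if parent_carriers[0] == fa else "maternal"
                else:
                    cls, origin = "rare_other", ("both" if fa_c and mo_c else
                                                 "paternal" if fa_c else "maternal")
                # one-family rule for biparental events
                rows.append({
                    "child": child.sample_id,
                    "sv_id": tid,
                    "chrom": rec.chrom,
                    "svtype": rec.svtype,
                    "category": classify_category(rec, cgt, child.sex),
                    "class": cls,
                    "origin": origin,
                })
        df = pd.DataFrame(rows, columns=["child", "sv_id", "chrom", "svtype",
                                         "category", "class", "origin"])
        if len(df):
            bip = df[df["class"] == "biparental_hom"]
            fam_of = {c.sample_id: c.family_id for c in self.pedigree.children}
            fams = bip.assign(fam=bip["child"].map(fam_of)).groupby("sv_id")["fam"].nunique()
            multi = set(fams[fams > 1].index)
            df.loc[df["sv_id"].isin(multi) & (df["class"] == "biparental_hom"), "class"] = "rare_other"
        return df


# ---------------------------------------------------------------------------
# generators

def _rng(cfg: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def _autosomes(cfg: SimulationConfig) -> list[str]:
    return [c for c in cfg.contigs if not is_sex_chrom(c)]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort: control panel, families,
    per-caller callsets and the ground-truth ledger."""
    rng = _rng(config, 1)
    placer = _LocusPlacer(_rng(config, 2), config)

    # ---- control panel loci ------------------------------------------------
    autosomes = _autosomes(config)
    n_x = int(round(config.n_common_sv * config.frac_x))
    n_y = int(round(config.n_common_sv * config.frac_y))
    n_auto = config.n_common_sv - n_x - n_y
    auto_weights = np.array([config.contigs[c] for c in autosomes], dtype=float)
    auto_weights /= auto_weights.sum()
    chrom_assignment = (
        list(rng.choice(autosomes, size=n_auto, p=auto_weights))
        + ["chrX"] * n_x + ["chrY"] * n_y
    )
    afs = rng.beta(config.af_beta[0], config.af_beta[1], size=config.n_common_sv)
    sizes = _sample_sizes(rng, config.n_common_sv, config)

    truth_records: dict[str, SVRecord] = {}
    truth_genotypes: dict[str, dict[str, Genotype]] = {}
    ledger_rows: list[dict] = []

    tr_flags = rng.random(config.n_common_sv) < config.tr_fraction
    for i, chrom in enumerate(chrom_assignment):
        tid = f"common_{i:05d}"
        rec = _draw_locus(rng, placer, config, chrom, tid, size=int(sizes[i]))
        truth_records[tid] = rec
        truth_genotypes[tid] = {}
        ledger_rows.append({
            "sv_id": tid, "chrom": rec.chrom, "pos": rec.pos, "svtype": rec.svtype,
            "svlen": rec.svlen, "af": float(afs[i]), "planted_class": "common",
            "family": "", "child": "", "origin": "", "tr": bool(tr_flags[i]),
        })

    # ---- control samples ---------------------------------------------------
    control_sexes, control_superpops = {}, {}
    for j in range(config.n_controls):
        s = f"ctrl_{j:04d}"
        control_sexes[s] = "male" if j % 2 == 0 else "female"
        control_superpops[s] = "AFR" if rng.random() < config.afr_fraction else "non-AFR"

    for i, row in enumerate(ledger_rows):
        tid = row["sv_id"]
        rec = truth_records[tid]
        for s in control_sexes:
            af = row["af"]
            if control_superpops[s] == "AFR":
                af = min(0.98, af * config.afr_af_boost)
            gt = _hw_genotype(rng, af, rec.chrom, control_sexes[s])
            if gt is not None and gt.has_alt:
                truth_genotypes[tid][s] = gt

    panel = GenotypeMatrix(
        loci=sorted(truth_records.values(), key=lambda r: (r.chrom, r.pos)),
        samples=list(control_sexes),
        genotypes={tid: dict(gts) for tid, gts in truth_genotypes.items()},
        provenance={},
    )

    # ---- families ----------------------------------------------------------
    ped_entries: list[PedigreeEntry] = []
    fam_superpop: dict[str, str] = {}
    for fi, spec in enumerate(config.families):
        fam = f"fam{fi:02d}"
        superpop = "AFR" if rng.random() < config.afr_fraction else "non-AFR"
        fam_superpop[fam] = superpop
        ped_entries.append(PedigreeEntry(f"{fam}_fa", fam, "father", "male", False, superpop))
        ped_entries.append(PedigreeEntry(f"{fam}_mo", fam, "mother", "female", False, superpop))
        for ci, sex in enumerate(spec.child_sexes):
            role = "proband" if ci == 0 else "sibling"
            ped_entries.append(
                PedigreeEntry(f"{fam}_{'p' if ci == 0 else 's'}{ci + 1}", fam, role,
                              sex, role == "proband", superpop)
            )
    pedigree = Pedigree(ped_entries)

    # parental genotypes at common loci, then Mendelian transmission
    for row in ledger_rows:
        tid, chrom = row["sv_id"], row["chrom"]
        af = row["af"]
        for fam in pedigree.families:
            members = pedigree.family_members(fam)
            fa = next(e for e in members if e.role == "father")
            mo = next(e for e in members if e.role == "mother")
            f_af = min(0.98, af * config.afr_af_boost) if fam_superpop[fam] == "AFR" else af
            fgt = _hw_genotype(rng, f_af, chrom, "male")
            mgt = _hw_genotype(rng, f_af, chrom, "female")
            gts = truth_genotypes[tid]
            if fgt is not None:
                gts[fa.sample_id] = fgt
            if mgt is not None:
                gts[mo.sample_id] = mgt
            for child in members:
                if not child.is_child:
                    continue
                cgt = _transmit(rng, fgt, mgt, chrom, child.sex)
                if cgt is not None:
                    gts[child.sample_id] = cgt

    # ---- planted family events --------------------------------------------
    plant_counter = 0

    def plant(chrom: str, kind: str, fam: str, child_id: str, origin: str,
              genotypes: dict[str, Genotype], tr: bool = False) -> str:
        nonlocal plant_counter
        tid = f"plant_{plant_counter:04d}"
        plant_counter += 1
        rec = _draw_locus(rng, placer, config, chrom, tid)
        truth_records[tid] = rec
        truth_genotypes[tid] = dict(genotypes)
        ledger_rows.append({
            "sv_id": tid, "chrom": rec.chrom, "pos": rec.pos, "svtype": rec.svtype,
            "svlen": rec.svlen, "af": 0.0, "planted_class": kind,
            "family": fam, "child": child_id, "origin": origin, "tr": tr,
        })
        return tid

    for fam in pedigree.families:
        members = pedigree.family_members(fam)
        fa = next(e.sample_id for e in members if e.role == "father")
        mo = next(e.sample_id for e in members if e.role == "mother")
        children = [e for e in members if e.is_child]

        for child in children:
            cid = child.sample_id
            for _ in range(config.n_denovo_per_child):
                chrom = str(rng.choice(autosomes))
                tr = bool(rng.random() < config.tr_fraction)
                plant(chrom, "de_novo", fam, cid, "none",
                      {cid: Genotype((0, 1))}, tr=tr)
            for _ in range(config.n_private_inherited):
                chrom = str(rng.choice(autosomes))
                parent, origin = (fa, "paternal") if rng.random() < 0.5 else (mo, "maternal")
                plant(chrom, "private_inherited", fam, cid, origin,
                      {parent: Genotype((0, 1)), cid: Genotype((0, 1))},
                      tr=bool(rng.random() < config.tr_fraction))
            if config.plant_x_private:
                cgt = Genotype((1,)) if child.sex == "male" else Genotype((0, 1))
                plant("chrX", "private_inherited", fam, cid, "maternal",
                      {mo: Genotype((0, 1)), cid: cgt})
            if config.plant_y_private and child.sex == "male":
                plant("chrY", "private_inherited", fam, cid, "paternal",
                      {fa: Genotype((1,)), cid: Genotype((1,))})
            if config.plant_x_hom and child.sex == "female":
                # inherited from carrier father (hemizygous) + het mother
                plant("chrX", "x_hom", fam, cid, "both",
                      {fa: Genotype((1,)), mo: Genotype((0, 1)), cid: Genotype((1, 1))})

        for _ in range(config.n_biparental_hom):
            chrom = str(rng.choice(autosomes))
            target = children[int(rng.integers(0, len(children)))]
            gts = {fa: Genotype((0, 1)), mo: Genotype((0, 1)),
                   target.sample_id: Genotype((1, 1))}
            for other in children:
                if other.sample_id == target.sample_id:
                    continue
                # Mendelian draw conditioned on not hom-alt (truth stays one-child)
                u = rng.random()
                gts[other.sample_id] = Genotype((0, 0)) if u < 1 / 3 else Genotype((0, 1))
            plant(chrom, "biparental_hom", fam, target.sample_id, "both", gts)

    # ---- per-caller callset emission ---------------------------------------
    trunc = config._jitter_trunc()
    cap_frac = (1.0 - config.params.pctseq) / 2.0
    callsets: dict[str, dict[str, list[SVRecord]]] = {
        s: {c: [] for c in config.caller_sensitivity} for s in pedigree.samples
    }
    call_genotypes: dict[str, dict[str, Genotype]] = {}
    genotype_errors: list[tuple[str, str]] = []

    order = sorted(truth_records)
    for tid in order:
        rec = truth_records[tid]
        gts = truth_genotypes[tid]
        for sample in pedigree.samples:
            true_gt = gts.get(sample)
            if true_gt is None or not true_gt.has_alt:
                continue
            emit_gt = true_gt
            if (config.genotype_error_rate > 0 and true_gt.ploidy == 2
                    and rng.random() < config.genotype_error_rate):
                emit_gt = Genotype((1, 1)) if true_gt.is_het else Genotype((0, 1))
                genotype_errors.append((sample, tid))
            for caller, sens in config.caller_sensitivity.items():
                if rng.random() >= sens:
                    continue
                jitter = int(np.clip(round(rng.normal(0, config.breakpoint_jitter_sd)),
                                     -trunc, trunc))
                pos = max(1, rec.pos + jitter)
                seq = (_mutate_seq(rng, rec.seq, config.seq_divergence, cap_frac)
                       if rec.seq is not None else None)
                cid = f"{tid}@{sample}@{caller}"
                call = SVRecord(id=cid, chrom=rec.chrom, pos=pos, svtype=rec.svtype,
                                svlen=rec.svlen, qual=float(np.round(rng.uniform(20, 60), 1)),
                                seq=seq, callers=frozenset([caller]), sample=sample)
                callsets[sample][caller].append(call)
                call_genotypes[cid] = {sample: emit_gt}

    for sample in callsets:
        for caller in callsets[sample]:
            callsets[sample][caller].sort(key=lambda r: (r.chrom, r.pos, r.id))

    ledger = pd.DataFrame(ledger_rows)
    return Cohort(
        config=config, panel=panel, control_sexes=control_sexes,
        control_superpops=control_superpops, pedigree=pedigree,
        truth_records=truth_records, truth_genotypes=truth_genotypes,
        ledger=ledger, callsets=callsets, call_genotypes=call_genotypes,
        genotype_errors=genotype_errors,
    )


# ---------------------------------------------------------------------------
# read support

def simulate_read_support(cohort: Cohort, seed_tag: int = 7) -> pd.DataFrame:
    """Parental read support for every non-common true locus.

    Carrier parents draw supporting reads from Poisson(lambda_carrier);
    non-carriers from Poisson(lambda_noise).  Mapping quality and clipping
    summaries feed the callable-region score.
    """
    cfg = cohort.config
    rng = _rng(cfg, 100 + seed_tag)
    rows = []
    for row in cohort.ledger.itertuples():
        if row.planted_class == "common":
            continue
        fam = row.family
        for e in cohort.pedigree.family_members(fam):
            if e.role not in ("father", "mother"):
                continue
            gt = cohort.truth_genotypes[row.sv_id].get(e.sample_id)
            carrier = gt is not None and gt.has_alt
            lam = cfg.lambda_carrier if carrier else cfg.lambda_noise
            n_reads = int(rng.poisson(lam)) if lam > 0 else 0
            rows.append({
                "sv_id": row.sv_id,
                "sample": e.sample_id,
                "n_reads": n_reads,
                "mean_mapq": float(np.round(rng.uniform(55, 60), 2)),
                "frac_clipped": float(np.round(rng.beta(1, 40), 4)),
            })
    return pd.DataFrame(rows, columns=["sv_id", "sample", "n_reads", "mean_mapq", "frac_clipped"])


def simulate_genotyper_calls(
    cohort: Cohort, miss_rate: float = 0.0, seed_tag: int = 8
) -> dict[str, dict[str, Genotype]]:
    """Parental re-genotyping at non-common loci: the true genotype,
    dropped with ``miss_rate``."""
    cfg = cohort.config
    rng = _rng(cfg, 200 + seed_tag)
    out: dict[str, dict[str, Genotype]] = {}
    for row in cohort.ledger.itertuples():
        if row.planted_class == "common":
            continue
        for e in cohort.pedigree.family_members(row.family):
            if e.role not in ("father", "mother"):
                continue
            if miss_rate > 0 and rng.random() < miss_rate:
                continue
            gt = cohort.truth_genotypes[row.sv_id].get(e.sample_id)
            if gt is not None:
                out.setdefault(row.sv_id, {})[e.sample_id] = gt
    return out


# ---------------------------------------------------------------------------
# assembly-to-reference alignments (PAF)

def simulate_alignments(
    n_contigs: int,
    chrom_length: int,
    seed: int = 0,
    chrom: str = "chrX",
    gap_prob: float = 0.0,
    mean_gap: int = 50_000,
    overlap: int = 0,
    qname_prefix: str = "contig",
) -> list[PafRecord]:
    """Contig-to-reference alignment blocks tiling a chromosome.

    The chromosome is split into ``n_contigs`` contiguous segments at
    random breakpoints; each junction optionally opens a coverage gap
    (``gap_prob``, exponential length ``mean_gap``) or an ``overlap`` bp
    double-covered stretch.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    cuts = sorted(rng.integers(1, chrom_length, size=n_contigs - 1).tolist())
    bounds = [0] + cuts + [chrom_length]
    records = []
    for i in range(n_contigs):
        start, end = bounds[i], bounds[i + 1]
        if i > 0 and gap_prob > 0 and rng.random() < gap_prob:
            start = min(end, start + int(rng.exponential(mean_gap)))
        if i > 0 and overlap > 0:
            start = max(0, start - overlap)
        if end <= start:
            continue
        qlen = end - start
        records.append(PafRecord(
            qname=f"{qname_prefix}_{i}", qlen=qlen, qstart=0, qend=qlen,
            strand="+", tname=chrom, tlen=chrom_length, tstart=start, tend=end,
            nmatch=qlen, alen=qlen, mapq=60,
        ))
    return records


# ---------------------------------------------------------------------------
# haplotype methylation pileups

def simulate_methylation(
    cpg_islands: pd.DataFrame,
    skew: float,
    noise_sd: float = 0.05,
    baseline: float = 0.5,
    cpg_per_island: int = 20,
    flank: int = 5_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two haplotype bedMethyl-style pileups over CpG islands (+/- flank).

    Haplotype-1 CpGs centre on ``baseline + skew/2`` and haplotype-2 on
    ``baseline - skew/2`` (clipped to [0, 1]); Gaussian per-CpG noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    haps: list[list[dict]] = [[], []]
    for isl in cpg_islands.itertuples():
        lo = max(0, int(isl.start) - flank)
        hi = int(isl.end) + flank
        positions = np.sort(rng.integers(lo, hi - 1, size=cpg_per_island))
        for h, sign in ((0, +0.5), (1, -0.5)):
            frac = np.clip(
                baseline + sign * skew + rng.normal(0, noise_sd, size=cpg_per_island),
                0.0, 1.0,
            )
            for p, f in zip(positions, frac):
                haps[h].append({
                    "chrom": isl.chrom, "start": int(p), "end": int(p) + 1,
                    "name": "m", "coverage": 20, "frac": float(np.round(f, 4)),
                })
    cols = ["chrom", "start", "end", "name", "coverage", "frac"]
    return pd.DataFrame(haps[0], columns=cols), pd.DataFrame(haps[1], columns=cols)


# ---------------------------------------------------------------------------
# TR genotyping table

def simulate_trgt(cohort: Cohort, len_jitter: int = 2, seed_tag: int = 9) -> pd.DataFrame:
    """Tandem-repeat allele lengths for TR-flagged non-common loci.

    Each family member gets one row per TR locus with its two (or one, when
    hemizygous) allele lengths: the variant allele length is the SV length
    (jittered by up to ``len_jitter`` bp), the reference allele 0.
    """
    cfg = cohort.config
    rng = _rng(cfg, 300 + seed_tag)
    tr_ids = set(cohort.ledger.loc[(cohort.ledger["tr"]) &
                                   (cohort.ledger["planted_class"] != "common"), "sv_id"])
    rows = []
    for tid in sorted(tr_ids):
        rec = cohort.truth_records[tid]
        fam = cohort.ledger.set_index("sv_id").loc[tid, "family"]
        for e in cohort.pedigree.family_members(fam):
            gt = cohort.truth_genotypes[tid].get(e.sample_id)
            alt_len = rec.svlen + int(rng.integers(-len_jitter, len_jitter + 1))
            if gt is None:
                continue
            lens = [alt_len if a == 1 else 0 for a in gt.alleles if a is not None]
            rows.append({
                "sv_id": tid, "sample": e.sample_id,
                "allele_lens": ",".join(str(x) for x in lens),
            })
    return pd.DataFrame(rows, columns=["sv_id", "sample", "allele_lens"])


# ---------------------------------------------------------------------------
# annotation tracks over the simulated loci

def simulate_tracks(cohort: Cohort, seed_tag: int = 10,
                    fractions: Optional[dict] = None):
    """Annotation tracks built over the simulated loci with known membership.

    Each track claims a disjoint-by-construction random subset of loci by
    covering their footprints, so every SV's expected label is known from
    the draw.  Returns (tracks, expected_membership: track class -> set of
    truth ids).
    """
    from svsieve.annotate import AnnotationTrack

    cfg = cohort.config
    rng = _rng(cfg, 400 + seed_tag)
    fractions = fractions or {
        "exon": 0.04, "utr": 0.03, "intron": 0.35,
        "promoter": 0.05, "enhancer": 0.08, "brain_reg": 0.06,
        "ndd_gene": 0.02, "segdup": 0.05,
    }
    ids = sorted(cohort.truth_records)
    membership: dict[str, set] = {}
    tracks = []
    for cls, frac in fractions.items():
        chosen = {tid for tid in ids if rng.random() < frac}
        membership[cls] = chosen
        intervals: dict[str, list[tuple]] = {}
        for tid in sorted(chosen):
            rec = cohort.truth_records[tid]
            s, e = rec.interval0()
            pad = 200  # swallow breakpoint jitter of member calls
            label = f"GENE_{tid}" if cls in ("exon", "utr", "intron", "ndd_gene") else None
            intervals.setdefault(rec.chrom, []).append((max(0, s - pad), e + pad, label))
        tracks.append(AnnotationTrack(name=cls, cls=cls, intervals=intervals))
    # TR track from the ledger flags
    tr_ids = set(cohort.ledger.loc[cohort.ledger["tr"], "sv_id"])
    intervals = {}
    for tid in sorted(tr_ids):
        rec = cohort.truth_records[tid]
        s, e = rec.interval0()
        intervals.setdefault(rec.chrom, []).append((max(0, s - 200), e + 200, None))
    tracks.append(AnnotationTrack(name="tr", cls="tr", intervals=intervals))
    membership["tr"] = tr_ids
    return tracks, membership
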