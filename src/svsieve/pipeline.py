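"""End-to-end orchestration: simulate -> validate -> collapse -> rare ->
curate -> annotate -> burden -> scaling curves.

Each stage is a thin call into the corresponding module; the pipeline
records per-stage counts in a machine-readable manifest so the headline
quantities (validated fraction, rare pool per child, category partition,
de novo counts) can be read off one JSON object.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from svsieve import io as svio
from svsieve.annotate import AnnotationTrack, annotate_all
from svsieve.burden import count_burden, discovery_curve, rare_pool_curve
from svsieve.merge import (
    GenotypeMatrix,
    collapse,
    mendelian_concordance,
    validate_callerset,
)
from svsieve.rarefilter import (
    classify_category,
    extract_biparental_hom,
    extract_private_inherited,
    filter_common,
)
from svsieve.sim import (
    Cohort,
    SimulationConfig,
    simulate_cohort,
    simulate_genotyper_calls,
    simulate_read_support,
    simulate_tracks,
    simulate_trgt,
)
from svsieve.transmission import (
    CallableScoreParams,
    FamilyEvidence,
    TransmissionVerdict,
    curate,
)
from svsieve.types import ALIGNER_A, ALIGNER_B, ASSEMBLY, Genotype, MergeParams

logger = logging.getLogger("svsieve")

GT_MISSING = Genotype((None, None))


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: Optional[Path] = None  # None: in-memory run, no files written
    score_params: CallableScoreParams = field(default_factory=CallableScoreParams)
    tr_tol_bp: int = 10
    tr_tol_frac: float = 0.1
    with_tracks: bool = True
    allow_no_controls: bool = False

    def __post_init__(self):
        if self.simulation.n_controls == 0 and not self.allow_no_controls:
            raise ValueError("zero controls requested while frequency filtering is enabled")


@dataclass
class PipelineResult:
    cohort: Cohort
    validated: dict[str, list]  # sample -> validated assembly calls
    matrix: GenotypeMatrix
    concordance: dict[str, float]
    mean_concordance: float
    rare_by_child: dict[str, list]
    categories: dict[tuple, str]
    class_labels: dict[tuple, object]
    verdicts: list[TransmissionVerdict]
    labels: dict[str, object]
    burden_table: pd.DataFrame
    curve: list[int]
    rare_curve: pd.DataFrame
    manifest: dict


def _truth_key(locus_id: str) -> str:
    return locus_id.split("@")[0]


def run_pipeline(config: RunConfig) -> PipelineResult:
    cfg = config.simulation
    params = cfg.params

    # ---- stage 1: simulate -------------------------------------------------
    cohort = simulate_cohort(cfg)
    support = simulate_read_support(cohort)
    genotyper = simulate_genotyper_calls(cohort)
    trgt = simulate_trgt(cohort)
    n_input = sum(len(cs) for s in cohort.callsets.values() for cs in s.values())

    # ---- stage 2: per-sample callerset validation --------------------------
    validated: dict[str, list] = {}
    for sample in cohort.pedigree.samples:
        sets = cohort.callsets[sample]
        v, _ = validate_callerset(
            sets.get(ASSEMBLY, []),
            [sets.get(ALIGNER_A, []), sets.get(ALIGNER_B, [])],
            params,
        )
        validated[sample] = v
    n_validated = sum(len(v) for v in validated.values())

    # ---- stage 3: cohort collapse into the nonredundant matrix -------------
    all_calls = sorted(
        (c for v in validated.values() for c in v),
        key=lambda r: (r.chrom, r.pos, r.id),
    )
    matrix = collapse(
        all_calls,
        MergeParams(**{**params.__dict__, "keep_rule": "common"}),
        genotypes=cohort.call_genotypes,
        samples=cohort.pedigree.samples,
    )

    # ---- stage 4: Mendelian concordance ------------------------------------
    concordance, mean_conc = mendelian_concordance(matrix, cohort.pedigree)

    # ---- stage 5: pangenome filtering + classification ---------------------
    rare_by_child: dict[str, list] = {}
    categories: dict[tuple, str] = {}
    for child in cohort.pedigree.children:
        child_loci = [l for l in matrix.loci
                      if (g := matrix.genotype(l.id, child.sample_id)) is not None and g.has_alt]
        rare = filter_common(child_loci, cohort.panel, child.sex, params,
                             control_sexes=cohort.control_sexes)
        rare_by_child[child.sample_id] = rare
        for sv in rare:
            gt = matrix.genotype(sv.id, child.sample_id)
            categories[(child.sample_id, sv.id)] = classify_category(sv, gt, child.sex)

    class_labels: dict[tuple, object] = {}
    class_labels.update(extract_private_inherited(rare_by_child, matrix, cohort.pedigree))
    class_labels.update(
        extract_biparental_hom(rare_by_child, matrix, cohort.pedigree,
                               control_matrix=cohort.panel, control_params=params)
    )

    # ---- stage 6: transmission curation ------------------------------------
    support_by_key = {
        (r.sv_id, r.sample): (float(r.n_reads), float(r.mean_mapq), float(r.frac_clipped))
        for r in support.itertuples()
    }
    trgt_by_key: dict[tuple, list[int]] = {}
    for r in trgt.itertuples():
        lens = [int(x) for x in str(r.allele_lens).split(",") if x != ""]
        trgt_by_key[(r.sv_id, r.sample)] = lens
    tr_ids = set(cohort.ledger.loc[cohort.ledger["tr"], "sv_id"])

    verdicts: list[TransmissionVerdict] = []
    for child in cohort.pedigree.children:
        cid = child.sample_id
        fam = child.family_id
        fa, mo = cohort.pedigree.parents_of(cid)
        raw = cohort.raw_parent_callsets(fam)
        for sv in rare_by_child[cid]:
            tid = _truth_key(sv.id)
            ev = FamilyEvidence(
                child_gt=matrix.genotype(sv.id, cid) or GT_MISSING,
                father_gt=matrix.genotype(sv.id, fa) or GT_MISSING,
                mother_gt=matrix.genotype(sv.id, mo) or GT_MISSING,
                child_sex=child.sex,
                parental_raw_callsets=raw,
                father=fa,
                mother=mo,
                read_support={
                    p: support_by_key[(tid, p)]
                    for p in (fa, mo) if (tid, p) in support_by_key
                },
                genotyper_calls={sv.id: genotyper.get(tid, {})},
                tr_flag=tid in tr_ids,
                child_tr_allele_len=(max(trgt_by_key.get((tid, cid), [0])) or None),
                parental_tr_allele_lens=(
                    trgt_by_key.get((tid, fa), []) + trgt_by_key.get((tid, mo), [])
                ),
            )
            verdicts.append(
                curate(sv, cid, ev, params=params, score_params=config.score_params,
                       tr_tol_bp=config.tr_tol_bp, tr_tol_frac=config.tr_tol_frac)
            )

    from svsieve.rarefilter import RareClassLabel

    for v in verdicts:
        key = (v.child, v.sv_id)
        if v.status == "de_novo":
            class_labels[key] = RareClassLabel("de_novo", "none")
        elif key not in class_labels or class_labels[key] is None:
            class_labels[key] = RareClassLabel("rare_other", v.origin)

    # ---- stage 7: annotation ----------------------------------------------
    tracks: list[AnnotationTrack] = []
    if config.with_tracks:
        tracks, _ = simulate_tracks(cohort)
    rare_loci = {sv.id: sv for loci in rare_by_child.values() for sv in loci}
    labels = annotate_all(list(rare_loci.values()), tracks)

    # ---- stage 8: burden + curves ------------------------------------------
    burden_table = count_burden(rare_by_child, categories, cohort.pedigree,
                                labels=labels, class_labels=class_labels)
    curve = discovery_curve(cohort.panel)
    child_sexes = {c.sample_id: c.sex for c in cohort.pedigree.children}
    panel_n = len(cohort.panel.samples)
    probe_sizes = sorted({0, panel_n // 4, panel_n // 2, panel_n})
    rare_curve = rare_pool_curve(
        rare_input_by_child={
            cid: [l for l in matrix.loci
                  if (g := matrix.genotype(l.id, cid)) is not None and g.has_alt]
            for cid in child_sexes
        },
        control_matrix=cohort.panel,
        child_sexes=child_sexes,
        params=params,
        control_sexes=cohort.control_sexes,
        panel_sizes=probe_sizes,
    )

    # ---- manifest ----------------------------------------------------------
    n_children = len(cohort.pedigree.children)
    carried_per_child = {
        cid: sum(1 for l in matrix.loci
                 if (g := matrix.genotype(l.id, cid)) is not None and g.has_alt)
        for cid in child_sexes
    }
    rare_per_child = {cid: len(v) for cid, v in rare_by_child.items()}
    frac_filtered = {
        cid: 1.0 - rare_per_child[cid] / carried_per_child[cid]
        for cid in child_sexes if carried_per_child[cid]
    }
    cat_counts: dict[str, int] = {}
    for cat in categories.values():
        cat_counts[cat] = cat_counts.get(cat, 0) + 1
    verdict_counts: dict[str, int] = {}
    for v in verdicts:
        verdict_counts[v.status] = verdict_counts.get(v.status, 0) + 1
    manifest = {
        "seed": cfg.seed,
        "n_samples": len(cohort.pedigree),
        "n_children": n_children,
        "n_controls": len(cohort.panel.samples),
        "n_input_calls": n_input,
        "n_validated_calls": n_validated,
        "validated_fraction": n_validated / max(1, sum(
            len(cohort.callsets[s].get(ASSEMBLY, [])) for s in cohort.pedigree.samples)),
        "n_nonredundant_loci": len(matrix.loci),
        "mean_mendelian_concordance": mean_conc,
        "mean_carried_per_child": sum(carried_per_child.values()) / n_children,
        "mean_rare_per_child": sum(rare_per_child.values()) / n_children,
        "mean_fraction_filtered": sum(frac_filtered.values()) / len(frac_filtered),
        "category_counts": cat_counts,
        "n_rare_total": sum(rare_per_child.values()),
        "verdict_counts": verdict_counts,
        "discovery_curve_end": curve[-1] if curve else 0,
    }

    result = PipelineResult(
        cohort=cohort, validated=validated, matrix=matrix,
        concordance=concordance, mean_concordance=mean_conc,
        rare_by_child=rare_by_child, categories=categories,
        class_labels=class_labels, verdicts=verdicts, labels=labels,
        burden_table=burden_table, curve=curve, rare_curve=rare_curve,
        manifest=manifest,
    )
    if config.outdir is not None:
        write_outputs(config, result, support)
    return result


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def write_outputs(config: RunConfig, result: PipelineResult, support: pd.DataFrame) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = result.cohort
    contigs = cohort.config.contigs

    svio.write_pedigree(out / "pedigree.tsv", cohort.pedigree)
    svio.write_sv_vcf(out / "controls.vcf", cohort.panel.loci,
                      genotypes=cohort.panel.genotypes,
                      samples=cohort.panel.samples, contigs=contigs)
    callset_dir = out / "callsets"
    callset_dir.mkdir(exist_ok=True)
    for sample, sets in cohort.callsets.items():
        for caller, calls in sets.items():
            svio.write_sv_vcf(callset_dir / f"{sample}.{caller}.vcf", calls,
                              genotypes={c.id: cohort.call_genotypes[c.id] for c in calls},
                              samples=[sample], contigs=contigs)
    svio.write_sv_vcf(out / "matrix.vcf", result.matrix.loci,
                      genotypes=result.matrix.genotypes,
                      samples=result.matrix.samples, contigs=contigs)
    svio.write_support_table(out / "read_support.tsv", support)
    cohort.ledger.to_csv(out / "truth_ledger.tsv", sep="\t", index=False)

    rare_rows = []
    for child, loci in result.rare_by_child.items():
        for sv in loci:
            cl = result.class_labels.get((child, sv.id))
            lab = result.labels.get(sv.id)
            rare_rows.append({
                "sv_id": sv.id, "child": child,
                "category": result.categories.get((child, sv.id), ""),
                "class": cl.value if cl is not None else "",
                "origin": cl.origin if cl is not None else "",
                "primary_class": lab.primary_class if lab is not None else "",
                "flags": ",".join(sorted(lab.flags)) if lab is not None else "",
            })
    pd.DataFrame(rare_rows, columns=["sv_id", "child", "category", "class",
                                     "origin", "primary_class", "flags"]
                 ).to_csv(out / "rare.tsv", sep="\t", index=False)

    pd.DataFrame([v.__dict__ for v in result.verdicts]).to_csv(
        out / "verdicts.tsv", sep="\t", index=False)
    result.burden_table.to_csv(out / "burden.tsv", sep="\t")
    pd.DataFrame({"k": range(1, len(result.curve) + 1), "cumulative": result.curve}
                 ).to_csv(out / "discovery_curve.tsv", sep="\t", index=False)
    result.rare_curve.to_csv(out / "rare_pool_curve.tsv", sep="\t", index=False)

    manifest = dict(result.manifest)
    manifest["checksums"] = {
        p.name: _checksum(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.vcf"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
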