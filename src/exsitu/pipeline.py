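"""End-to-end captive-ancestry pipeline.

Fixed stage order: QC culling -> allele frequencies -> mtDNA haplotype
matching -> partial-Bayesian assignment (L1/L2 + exclusion) -> supervised
admixture -> hybrid-class classification -> relatedness/parentage. Every
stage writes its artifact to the output directory, a machine-readable
manifest records versions, seed and a parameter hash, and the global seed
propagates deterministically (one spawned stream per stage), so a rerun with
the same config reproduces every output.

The per-individual report mirrors the field's summary tables: maternal
(mtDNA) assignment with native/non-native status, nuclear best population
with membership coefficient q, L1/L2 likelihood ranking, exclusion set,
hybrid-class call, and a congruence flag — true when the mtDNA island group
and the nuclear best population's island group agree. An individual is
*mixed* when those disagree or when its compatible hybrid-class set excludes
both parental classes; membership in the configured target lineage is called
from the target population's q and the L1 assignment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import AdmixtureModel, McmcParams
from .assignment import AssignmentModel
from .datamodel import GenotypeDataset, compute_allele_frequencies
from .genepop import apply_metadata, read_genepop
from .hybrids import build_class_distributions, classify_by_q
from .mtdna import HaplotypeDB, classify_native_status, match_haplotype
from .qc import cull_flagged, screen_dataset
from .relatedness import (
    build_dyad_distributions,
    classify_dyad,
    parentage_compatible,
    relatedness_matrix,
)

logger = logging.getLogger("exsitu.pipeline")

STAGES = ("qc", "mtdna", "assignment", "admixture", "target", "hybrids", "relatedness")


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters; loadable from YAML."""

    # inputs (file-based runs; in-memory runs pass objects directly)
    genotypes: str | None = None
    pop_names: str | None = None
    metadata: str | None = None
    mtdna_fasta: str | None = None
    mtdna_metadata: str | None = None
    query_mtdna_fasta: str | None = None

    output_dir: str = "exsitu_out"
    seed: int = 0

    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    # QC
    qc_alpha: float = 0.05
    qc_reps: int = 2000

    # assignment
    assign_n_sim: int = 10_000
    assign_threshold: float = 0.01

    # admixture
    mcmc: McmcParams = field(default_factory=McmcParams)

    # hybrid classes
    hybrid_pairs: list[tuple[str, str]] = field(default_factory=list)
    hybrid_third_population: str | None = None
    n_per_class: int = 500

    # relatedness
    dyad_n: int = 1000
    mismatch_tolerance: int = 0

    # target-lineage screen
    target_population: str | None = None
    q_target_threshold: float = 0.35
    n_target_null: int = 5000  # bootstrap purebred nulls per companion pop
    target_null_percentile: float = 99.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = McmcParams(**raw["mcmc"])
        if "hybrid_pairs" in raw:
            raw["hybrid_pairs"] = [tuple(p) for p in raw["hybrid_pairs"]]
        cfg = cls(**raw)
        return cfg

    def parameter_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: pd.DataFrame
    artifacts: dict[str, object]
    manifest: dict

    def mixed(self) -> pd.DataFrame:
        return detect_mixed_ancestry(self.report)

    def target_members(self) -> pd.DataFrame:
        if "target_member" not in self.report.columns:
            return self.report.iloc[0:0]
        return self.report[self.report["target_member"]]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(STAGES, ss)
    }


def run_full_pipeline(
    dataset: GenotypeDataset,
    config: RunConfig,
    haplotype_db: HaplotypeDB | None = None,
    island_of: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every enabled stage on an in-memory dataset.

    ``island_of`` maps populations to island groups for the congruence flag;
    unmapped populations are treated as their own group.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    island_of = island_of or {}
    isl = lambda pop: island_of.get(pop, pop)
    artifacts: dict[str, object] = {}
    counts: dict[str, int] = {}
    unknowns = dataset.unknown_ids
    if not unknowns:
        logger.warning("no unknown-origin individuals in dataset")

    def fail(stage: str, exc: Exception, record: str = "") -> Exception:
        return RuntimeError(
            f"pipeline stage '{stage}' failed{f' at {record}' if record else ''}: {exc}"
        )

    # -- QC --------------------------------------------------------------
    working = dataset
    if config.stages.get("qc", True):
        try:
            qc_report = screen_dataset(
                dataset, reps=config.qc_reps, alpha=config.qc_alpha,
                seed=seeds["qc"],
            )
            working = cull_flagged(dataset, qc_report)
        except Exception as e:  # pragma: no cover - defensive
            raise fail("qc", e)
        qc_report.to_tsv(outdir / "qc_report.tsv")
        artifacts["qc"] = qc_report
        counts["qc_flagged_cells"] = len(qc_report.flagged_cells)
        logger.info("qc: %d cells flagged, missingness %.4f -> %.4f",
                    len(qc_report.flagged_cells), dataset.missing_fraction(),
                    working.missing_fraction())

    table = compute_allele_frequencies(working)
    artifacts["frequencies"] = table

    report = pd.DataFrame({"individual_id": unknowns})
    report["sex"] = [working.sex[working.row(i)] for i in unknowns]

    # -- mtDNA -----------------------------------------------------------
    if config.stages.get("mtdna", True) and haplotype_db is not None:
        rows = []
        for iid in unknowns:
            seq = working.mtdna[working.row(iid)]
            if seq is None:
                rows.append(dict(individual_id=iid, mtdna_haplotype="",
                                 mtdna_pops="", mtdna_islands="",
                                 mtdna_native="", mtdna_distance=np.nan))
                continue
            try:
                m = match_haplotype(seq, haplotype_db, query_id=iid)
            except Exception as e:
                raise fail("mtdna", e, iid)
            primary_pop = sorted(m.populations)[0]
            rows.append(dict(
                individual_id=iid,
                mtdna_haplotype=",".join(sorted(m.haplotype_ids)),
                mtdna_pops=",".join(sorted(m.populations)),
                mtdna_islands=",".join(sorted(m.islands)),
                mtdna_native=classify_native_status(m, haplotype_db, primary_pop),
                mtdna_distance=m.distance,
            ))
        mt = pd.DataFrame(rows)
        mt.to_csv(outdir / "mtdna_matches.tsv", sep="\t", index=False)
        report = report.merge(mt, on="individual_id", how="left")
        artifacts["mtdna"] = mt
        counts["mtdna_matched"] = int((mt["mtdna_haplotype"] != "").sum())

    # -- assignment --------------------------------------------------------
    if config.stages.get("assignment", True) and unknowns:
        model = AssignmentModel(table)
        try:
            asg = model.assign_dataset(
                working, exclusion=True, n_sim=config.assign_n_sim,
                threshold=config.assign_threshold, seed=seeds["assignment"],
            )
        except Exception as e:
            raise fail("assignment", e)
        asg.to_tsv(outdir / "assignment.tsv")
        artifacts["assignment"] = asg
        sub = asg.summary()[["individual_id", "L1_pop", "L1_score",
                             "L2_pop", "L2_score", "excluded"]]
        report = report.merge(sub, on="individual_id", how="left")
        counts["assigned"] = len(asg.records)

    # -- admixture ---------------------------------------------------------
    admix = None
    if config.stages.get("admixture", True) and unknowns:
        params = McmcParams(
            burn_in=config.mcmc.burn_in, reps=config.mcmc.reps,
            alpha=config.mcmc.alpha, lam=config.mcmc.lam,
            thin=config.mcmc.thin, seed=seeds["admixture"],
        )
        try:
            admix = AdmixtureModel.from_dataset(working, unknowns).fit(params)
        except Exception as e:
            raise fail("admixture", e)
        admix.to_tsv(outdir / "admixture.tsv")
        artifacts["admixture"] = admix
        qbest, qpop, qtarget = [], [], []
        for iid in unknowns:
            if iid in admix.excluded_ids:
                qbest.append(np.nan)
                qpop.append("")
                qtarget.append(np.nan)
                continue
            q = admix.q(iid)
            qbest.append(float(q.max()))
            qpop.append(admix.populations[int(np.argmax(q))])
            if config.target_population in admix.populations:
                qtarget.append(float(q[admix.populations.index(config.target_population)]))
            else:
                qtarget.append(np.nan)
        report["q_best_pop"] = qpop
        report["q_best"] = qbest
        if config.target_population:
            report[f"q_{config.target_population}"] = qtarget
        counts["admixture_fitted"] = len(admix.ids)

    # -- target-lineage screen ---------------------------------------------
    # Likelihood-ratio screen: for each unknown, "F1(target, best
    # non-target population)" vs "purebred of that population", calibrated
    # against simulated and leave-one-out purebred nulls (see screen module).
    if (
        config.stages.get("target", True)
        and config.target_population
        and unknowns
        and "assignment" in artifacts
    ):
        tgt = config.target_population
        if tgt not in table.populations:
            raise fail("target", ValueError(f"unknown target population {tgt!r}"))
        from .screen import target_ancestry_screen

        asg = artifacts["assignment"]
        companions = {
            iid: next(p for p, _ in asg[iid].ranked if p != tgt)
            for iid in unknowns
        }
        try:
            scr = target_ancestry_screen(
                working, table, companions, tgt,
                n_null=config.n_target_null,
                percentile=config.target_null_percentile,
                seed=seeds["target"],
            )
        except Exception as e:
            raise fail("target", e)
        scr.table.to_csv(outdir / "target_screen.tsv", sep="\t", index=False)
        artifacts["target_screen"] = scr
        report = report.merge(
            scr.table.rename(columns={
                "lr": "target_lr", "cutoff": "target_lr_cutoff",
                "flagged": "target_lr_flag", "companion": "target_companion",
            }),
            on="individual_id", how="left",
        )
        counts["target_screened"] = len(scr.table)

    # -- hybrid classes ------------------------------------------------------
    if config.stages.get("hybrids", True) and config.hybrid_pairs and unknowns:
        mcmc = McmcParams(
            burn_in=config.mcmc.burn_in, reps=config.mcmc.reps,
            alpha=config.mcmc.alpha, lam=config.mcmc.lam,
            thin=config.mcmc.thin, seed=seeds["hybrids"],
        )
        try:
            dists = build_class_distributions(
                working, config.hybrid_pairs, n_per_class=config.n_per_class,
                mcmc=mcmc, third_population=config.hybrid_third_population,
                table=table,
            )
            pair = config.hybrid_pairs[0]
            pops = dists[pair].populations
            sub_rows = [working.row(i) for i in unknowns]
            pair_fit = AdmixtureModel(
                _pair_table(table, pops), working.G[sub_rows], unknowns
            ).fit(mcmc)
            point, compat = [], []
            for iid in unknowns:
                if iid in pair_fit.excluded_ids:
                    point.append("")
                    compat.append("")
                    continue
                ca = classify_by_q(pair_fit.q(iid), dists[pair], iid)
                point.append(ca.point_class)
                compat.append(",".join(ca.compatible_classes))
        except Exception as e:
            raise fail("hybrids", e)
        pd.concat([d.to_frame() for d in dists.values()]).to_csv(
            outdir / "class_distributions.tsv", sep="\t", index=False
        )
        artifacts["hybrid_distributions"] = dists
        artifacts["hybrid_pair_fit"] = pair_fit
        report["hybrid_point_class"] = point
        report["hybrid_compatible"] = compat
        counts["hybrid_classified"] = len(unknowns)

    # -- relatedness ---------------------------------------------------------
    if config.stages.get("relatedness", True) and len(unknowns) >= 2:
        try:
            matrix = relatedness_matrix(unknowns, working, unknowns,
                                        leave_one_out=True)
            # dyad nulls from the colony-wide frequencies
            colony = working.copy()
            for iid in unknowns:
                colony.populations[colony.row(iid)] = "colony"
            colony_table = compute_allele_frequencies(colony, subset=unknowns,
                                                      populations=["colony"])
            freqs = colony_table.freqs[0]
            dyads = build_dyad_distributions(freqs, n=config.dyad_n,
                                             seed=seeds["relatedness"])
        except Exception as e:
            raise fail("relatedness", e)
        matrix.to_tsv(outdir / "relatedness_matrix.tsv")
        dyads.to_frame().to_csv(outdir / "dyad_distributions.tsv", sep="\t",
                                index=False)
        artifacts["relatedness"] = matrix
        artifacts["dyads"] = dyads
        counts["relatedness_pairs"] = len(unknowns) * (len(unknowns) - 1) // 2

        pairs_rows = []
        for i, a in enumerate(unknowns):
            for b in unknowns[i + 1:]:
                r = matrix.value(a, b)
                if np.isnan(r):
                    continue
                best, compat = classify_dyad(r, dyads)
                pairs_rows.append(dict(id1=a, id2=b, r=r, best_class=best,
                                       compatible=",".join(compat)))
        pd.DataFrame(pairs_rows).to_csv(outdir / "dyad_classification.tsv",
                                        sep="\t", index=False)
        artifacts["dyad_classification"] = pd.DataFrame(pairs_rows)

        # Mendelian parentage screen among the colony (dams/sires vs others)
        par_rows = []
        for cand in unknowns:
            ci = working.individual(cand)
            for off in unknowns:
                if off == cand:
                    continue
                oi = working.individual(off)
                try:
                    ok, mm = parentage_compatible(
                        ci, oi, require_mtdna_for_maternity=True,
                        mismatch_tolerance=config.mismatch_tolerance,
                    )
                except ValueError:
                    continue
                if ok:
                    par_rows.append(dict(candidate_parent=cand, offspring=off,
                                         mismatching_loci=len(mm)))
        pd.DataFrame(par_rows).to_csv(outdir / "parentage_compatible.tsv",
                                      sep="\t", index=False)
        artifacts["parentage"] = pd.DataFrame(par_rows)

    # -- flags -----------------------------------------------------------
    report = _add_flags(report, config, isl)
    report.to_csv(outdir / "ancestry_report.tsv", sep="\t", index=False)

    manifest = {
        "exsitu_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stage_seeds": seeds,
        "counts": counts,
        "n_unknowns": len(unknowns),
        "n_reference": dataset.n_individuals - len(unknowns),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(report, artifacts, manifest)


def _pair_table(table, pops):
    from .datamodel import AlleleFrequencyTable

    rows = [table.pop_row(p) for p in pops]
    return AlleleFrequencyTable(pops, table.loci, table.counts[rows])


def _add_flags(report: pd.DataFrame, config: RunConfig, isl) -> pd.DataFrame:
    report = report.copy()
    have_mt = "mtdna_pops" in report.columns
    have_q = "q_best_pop" in report.columns
    congruent, mixed, target = [], [], []
    for _, row in report.iterrows():
        c = None
        if have_mt and have_q and row.get("mtdna_pops") and row.get("q_best_pop"):
            mt_islands = {
                isl(p) for p in str(row["mtdna_pops"]).split(",") if p
            } | set(str(row.get("mtdna_islands", "")).split(","))
            c = isl(row["q_best_pop"]) in mt_islands
        congruent.append(c)
        m = bool(c is False)
        compat = str(row.get("hybrid_compatible", "") or "")
        if compat:
            classes = set(compat.split(","))
            if not classes & {"parental_A", "parental_B"}:
                m = True
        mixed.append(m)
        t = False
        if config.target_population:
            tp = config.target_population
            qt = row.get(f"q_{tp}", np.nan)
            if pd.notna(qt) and qt >= config.q_target_threshold:
                t = True
            if row.get("L1_pop") == tp:
                t = True
            if bool(row.get("target_lr_flag", False)):
                t = True
        target.append(t)
    report["congruent"] = congruent
    report["mixed"] = mixed
    if config.target_population:
        report["target_member"] = target
    return report


def detect_mixed_ancestry(report: pd.DataFrame) -> pd.DataFrame:
    """Rows flagged as mixed: the mtDNA and nuclear best assignments
    disagree at the island level, or the compatible hybrid-class set
    excludes both parental classes."""
    if report.empty or "mixed" not in report.columns:
        return report.iloc[0:0]
    return report[report["mixed"]]


def run_from_files(config: RunConfig) -> PipelineResult:
    """File-based entry: read GENEPOP genotypes (+ sidecars) and the
    haplotype database, attach query mtDNA sequences, and run."""
    if not config.genotypes:
        raise ValueError("config.genotypes is required for file-based runs")
    dataset = read_genepop(config.genotypes, pop_names=config.pop_names)
    if config.metadata:
        dataset = apply_metadata(dataset, config.metadata)
    db = None
    if config.mtdna_fasta and config.mtdna_metadata:
        db = HaplotypeDB.from_files(config.mtdna_fasta, config.mtdna_metadata)
    if config.query_mtdna_fasta:
        from Bio import SeqIO

        for rec in SeqIO.parse(config.query_mtdna_fasta, "fasta"):
            if rec.id in dataset._index:
                dataset.mtdna[dataset.row(rec.id)] = str(rec.seq).upper()
    return run_full_pipeline(dataset, config, haplotype_db=db)
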