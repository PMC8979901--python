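"""End-to-end orchestration: simulate -> QC -> matrices -> fit -> GWAS -> report.

A run is driven by one :class:`RunConfig` (flat ``key = value`` text file
plus programmatic overrides), writes every artifact into a run directory,
and records a manifest with parameter values, content hashes and the seed
so that identical configs reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_qc import impute_missing, qc_filter
from .gwas import build_loco_grms, mlma_loco, significance_thresholds
from .io_formats import (
    Pedigree,
    read_genotypes,
    read_pedigree,
    read_phenotypes,
    write_genotypes,
    write_pedigree,
    write_phenotypes,
    write_results,
)
from .relationship_matrices import (
    a22 as build_a22,
    a_inverse,
    blend_g,
    genomic_relationship,
    grm_pca,
    h_inverse,
    h_matrix,
    numerator_relationship,
)
from .ssgblup import GibbsPriors, build_design, fit_gibbs, reliabilities
from .synthetic_data import (
    SimConfig,
    paper_shaped_config,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)

logger = logging.getLogger("ssgeval.pipeline")

STAGES = ("simulate", "qc", "relmat", "fit", "gwas", "report")


@dataclass
class RunConfig:
    """One serialisable source of truth for a pipeline run."""

    out_dir: str
    seed: int
    stages: tuple = STAGES
    # simulator
    simulate: bool = True
    sim_scale: float = 0.25
    markers_per_chrom: int = 200
    # external inputs (used when simulate=False)
    pedigree_path: str | None = None
    genotype_prefix: str | None = None
    genotype_format: str = "ped/map"
    phenotype_path: str | None = None
    # QC
    maf_min: float = 0.01
    callrate_min: float = 0.90
    hwe_p_min: float = 0.001
    # matrices
    blend_weight: float = 0.95
    # sampler
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    pedigree_only: bool = False
    # gwas
    run_conditional: bool = True
    condition_on: tuple = ()
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory when any stochastic stage is enabled")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.simulate:
            for name, p in (
                ("pedigree_path", self.pedigree_path),
                ("genotype_prefix", self.genotype_prefix),
                ("phenotype_path", self.phenotype_path),
            ):
                if p is None:
                    raise ValueError(f"simulator disabled but {name} not set")
                probe = Path(p if name != "genotype_prefix" else p + ".map")
                if not probe.exists():
                    raise ValueError(f"{name} does not exist: {probe}")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config file (one key per line)."""
        kv: dict = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise ValueError(f"config line is not 'key = value': {ln!r}")
            k, v = (x.strip() for x in ln.split("=", 1))
            kv[k] = v
        kv.update(overrides)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        parsed: dict = {}
        for k, v in kv.items():
            if k not in fields:
                raise ValueError(f"unknown config key '{k}'")
            if isinstance(v, str):
                t = fields[k].type
                if k in ("stages", "condition_on"):
                    v = tuple(x for x in v.replace(",", " ").split() if x)
                elif t in ("int", int):
                    v = int(v)
                elif t in ("float", float):
                    v = float(v)
                elif t in ("bool", bool):
                    v = v.lower() in ("1", "true", "yes")
            parsed[k] = v
        return cls(**parsed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Any stage failure leaves a ``FAILED`` marker (naming the stage) next
    to the partial outputs and re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    logging.getLogger("ssgeval").addHandler(fh)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            if stage == "simulate" and not config.simulate:
                continue
            logger.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, out, state)
            manifest["stages"].append(stage)
    except Exception as e:
        (out / "FAILED").write_text(f"{stage}: {e}\n")
        raise
    finally:
        logging.getLogger("ssgeval").removeHandler(fh)
        fh.close()
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    sim = paper_shaped_config(
        seed=config.seed,
        scale=config.sim_scale,
        markers_per_chrom=config.markers_per_chrom,
    )
    ped = simulate_pedigree(sim)
    cohort = ped.leaf_females()
    geno = simulate_genotypes(ped, sim, animals=cohort)
    phen = simulate_phenotypes(ped, geno, sim, animals=cohort)
    write_pedigree(ped, out / "pedigree.tsv")
    write_genotypes(geno, out / "genotypes", format=config.genotype_format)
    write_phenotypes(phen, out / "phenotypes.tsv")
    state.update(pedigree=ped, genotypes=geno, phenotypes=phen, sim=sim)


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "pedigree" not in state:
        state["pedigree"] = read_pedigree(config.pedigree_path)
    if "genotypes" not in state:
        state["genotypes"] = read_genotypes(
            config.genotype_prefix, format=config.genotype_format
        )
    if "phenotypes" not in state:
        state["phenotypes"] = read_phenotypes(
            config.phenotype_path, state["pedigree"]
        )


def _stage_qc(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, state)
    g, report = qc_filter(
        state["genotypes"],
        maf_min=config.maf_min,
        callrate_min=config.callrate_min,
        hwe_p_min=config.hwe_p_min,
    )
    g = impute_missing(g, seed=config.seed + 1)
    report.to_tsv(out / "qc_report.tsv")
    state["genotypes_qc"] = g
    state["qc_report"] = report


def _stage_relmat(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, state)
    ped: Pedigree = state["pedigree"]
    g = state.get("genotypes_qc") or state["genotypes"]
    A = numerator_relationship(ped)
    Ainv = a_inverse(ped)
    genotyped = [a for a in ped.ids if a in set(g.animal_ids)]
    g = g.subset_animals(genotyped)
    A22 = build_a22(ped, genotyped)
    Graw = genomic_relationship(g)
    Gb = blend_g(Graw, A22, weight=config.blend_weight)
    Ginv_vals = np.linalg.inv(Gb.values)
    A22inv_vals = np.linalg.inv(A22.values)
    from .relationship_matrices import RelationshipMatrix

    Hinv = h_inverse(
        Ainv,
        RelationshipMatrix("H_inverse", genotyped, Ginv_vals),
        RelationshipMatrix("H_inverse", genotyped, A22inv_vals),
        genotyped,
    )
    H, L = h_matrix(A, Gb, genotyped)
    logger.info(
        "H condition number %.3e", np.linalg.cond(H.values)
    )
    scores, fractions = grm_pca(Gb, n_components=2)
    pd.DataFrame(
        {
            "animal_id": genotyped,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
        }
    ).to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    (out / "pca_variance.tsv").write_text(
        "component\tfraction\n"
        + "".join(f"PC{i+1}\t{f:.6g}\n" for i, f in enumerate(fractions))
    )
    state.update(A=A, Ainv=Ainv, A22=A22, G=Gb, Hinv=Hinv, H=H, L=L,
                 genotyped=genotyped, genotypes_qc=g)


def _stage_fit(config: RunConfig, out: Path, state: dict) -> None:
    ped: Pedigree = state["pedigree"]
    if config.pedigree_only:
        # classical BLUP: H collapses to A
        L = np.linalg.cholesky(
            state["A"].values + 1e-8 * np.eye(len(ped))
        )
        from .relationship_matrices import RelationshipMatrix

        Lrm = RelationshipMatrix("H_cholesky", list(ped.ids), L)
    else:
        Lrm = state["L"]
    design = build_design(state["phenotypes"], ped, Lrm)
    fit = fit_gibbs(
        design,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed + 2,
        priors=GibbsPriors(),
    )
    write_results(fit, out / "ebv.tsv")
    rel = reliabilities(fit)
    with open(out / "fit_summary.txt", "w") as fhd:
        fhd.write("single-step animal model fit\n")
        fhd.write(f"sigma2_a\t{fit.sigma2_a:.6g}\t+-\t{fit.sigma2_a_sd:.3g}\n")
        fhd.write(f"sigma2_e\t{fit.sigma2_e:.6g}\t+-\t{fit.sigma2_e_sd:.3g}\n")
        fhd.write(f"h2\t{fit.h2:.4f}\t+-\t{fit.h2_sd:.3g}\n")
        for lab, bv, sd in zip(fit.b_labels, fit.b, fit.b_sd):
            fhd.write(f"b[{lab}]\t{bv:.6g}\t+-\t{sd:.3g}\n")
        fhd.write(
            f"chain\t{fit.n_iter} iter, burn-in {fit.burn_in}, thin {fit.thin}\n"
        )
        for k, v in fit.ess.items():
            fhd.write(f"ess[{k}]\t{v:.1f}\n")
        fhd.write(f"mean_reliability\t{rel.mean():.4f}\n")
    state["fit"] = fit


def _stage_gwas(config: RunConfig, out: Path, state: dict) -> None:
    g = state["genotypes_qc"]
    phen = state["phenotypes"]
    # phenotyped animals that are genotyped, in genotype order
    ids = [a for a in g.animal_ids if a in set(phen.animal_ids)]
    g = g.subset_animals(ids)
    df = phen.data.set_index("animal_id").loc[ids]
    y = df["height"].to_numpy(float)
    cls = df["age_class"].to_numpy()
    X = np.column_stack(
        [np.ones(len(y))]
        + [(cls == k).astype(float) for k in (2, 3, 4, 5) if (cls == k).any()]
    )
    loco = build_loco_grms(g)
    res = mlma_loco(y, X, g, loco)
    write_results(res, out / "gwas.tsv")
    (p05, p01), _ = significance_thresholds(int(res.table["p"].notna().sum()))
    state["gwas"] = res
    state["gwas_design"] = (y, X, g, loco)
    if config.run_conditional:
        cond = list(config.condition_on)
        if not cond:
            top = res.table.loc[res.table["p"].idxmin()]
            if top["p"] < p05:
                cond = [top["snp_id"]]
        if cond:
            res_c = mlma_loco(y, X, g, loco, conditioning=cond)
            write_results(res_c, out / "gwas_conditional.tsv")
            state["gwas_conditional"] = res_c


def _stage_report(config: RunConfig, out: Path, state: dict) -> None:
    report = report_summary_from_state(state)
    (out / "report.txt").write_text(report)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "relmat": _stage_relmat,
    "fit": _stage_fit,
    "gwas": _stage_gwas,
    "report": _stage_report,
}


def report_summary_from_state(state: dict) -> str:
    """Assemble the text report from in-memory stage outputs."""
    if "fit" not in state:
        raise ValueError("missing stage outputs: fit")
    ped: Pedigree = state["pedigree"]
    phen = state["phenotypes"]
    fit = state["fit"]
    rel = reliabilities(fit)
    lines = ["== phenotype summary by breed =="]
    df = phen.data.copy()
    breed_of = dict(zip(ped.ids, ped.breed))
    df["breed"] = df["animal_id"].map(breed_of)
    lines.append("breed\tn\tmean\tsd\tmin\tmax")
    for breed, grp in df.groupby("breed"):
        h = grp["height"]
        lines.append(
            f"{breed}\t{len(grp)}\t{h.mean():.1f}\t{h.std():.1f}"
            f"\t{h.min():.1f}\t{h.max():.1f}"
        )
    h = df["height"]
    lines.append(
        f"Total\t{len(df)}\t{h.mean():.1f}\t{h.std():.1f}\t{h.min():.1f}\t{h.max():.1f}"
    )
    lines.append("")
    lines.append("== variance components ==")
    lines.append(f"sigma2_a\t{fit.sigma2_a:.4g}")
    lines.append(f"sigma2_e\t{fit.sigma2_e:.4g}")
    h2sd = f"\t+-\t{fit.h2_sd:.3g}" if fit.h2_sd is not None else ""
    lines.append(f"h2\t{fit.h2:.4f}{h2sd}")
    lines.append("")
    lines.append("== reliability by information stratum ==")
    lines.append("stratum\tn\tmean\tmin\tmax")
    phenotyped = set(phen.animal_ids)
    genotyped = set(state.get("genotyped", phenotyped))
    strata = {
        "all": list(ped.ids),
        "no_genotype_no_phenotype": [
            a for a in ped.ids if a not in phenotyped and a not in genotyped
        ],
        "genotyped_and_phenotyped": [
            a for a in ped.ids if a in phenotyped and a in genotyped
        ],
    }
    pos = {a: i for i, a in enumerate(fit.animal_ids)}
    for name, animals in strata.items():
        if not animals:
            lines.append(f"{name}\t0\tNA\tNA\tNA")
            continue
        r = rel[[pos[a] for a in animals]]
        lines.append(
            f"{name}\t{len(animals)}\t{r.mean():.3f}\t{r.min():.3f}\t{r.max():.3f}"
        )
    return "\n".join(lines) + "\n"


def report_summary(run_dir) -> str:
    """Re-emit the text report from a completed run directory."""
    run_dir = Path(run_dir)
    report = run_dir / "report.txt"
    if not report.exists():
        raise ValueError("missing stage outputs: report (run the pipeline first)")
    return report.read_text()
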