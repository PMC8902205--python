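"""Pipeline orchestration and report rendering.

``run_pipeline`` executes the full analysis in the order a candidate-gene
study reports it — per-locus diversity, pairwise LD, multi-locus
haplotype estimation and filtering, diplotype assignment, then
marker-level and diplotype-level trait association — and writes every
artifact as TSV plus a run log.  All computation is carried out in full
precision; rounding happens only at render time (frequencies to 2 d.p.,
diversity and LD statistics to 3 d.p., trait means to 2 d.p., haplotype
frequencies as percentages), so re-running with the same configuration
and seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import AssociationReport, association_report
from .errors import CandgeneError, ValidationError
from .io import Dataset, load_dataset, TRAIT_NAMES, write_dataset
from .ld import (
    HaplotypeSet,
    LdMatrixResult,
    assign_diplotypes,
    em_haplotype_frequencies,
    filter_haplotypes,
    ld_matrix,
)
from .popgen import DF_MODE_DEFAULT, LocusStats, summarize_loci
from .synthpop import SimConfig, simulate_dataset

DIPLOTYPE_COLUMN = "diplotype_class"


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the flat key=value file format in the CLI."""

    genotype_path: str | None = None
    trait_path: str | None = None
    panel_path: str | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    hwe_df_mode: str = DF_MODE_DEFAULT
    min_hap_freq: float = 0.05
    min_class_freq: float = 0.05
    alpha: float = 0.05
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_restarts: int = 5
    seed: int = 0
    out_dir: str = "candgene_out"

    def validate(self) -> None:
        for name, v in (("min_hap_freq", self.min_hap_freq),
                        ("min_class_freq", self.min_class_freq)):
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not self.simulate and self.genotype_path is None:
            raise ValidationError("either set simulate=true or give a genotype_path")


@dataclass
class ReportBundle:
    """Everything one pipeline run computed."""

    dataset: Dataset
    locus_stats: list[LocusStats]
    ld: LdMatrixResult
    haplotypes_full: HaplotypeSet
    haplotypes: HaplotypeSet  # after the frequency filter
    diplotype_assignments: list
    diplotype_class_freqs: dict[str, float]
    retained_classes: dict[str, float]
    association: AssociationReport
    config: PipelineConfig


def _fmt(x: float, nd: int) -> str:
    return "nan" if pd.isna(x) else f"{x:.{nd}f}"


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; any stage error aborts with the stage name attached."""
    config.validate()
    stage = "load"
    try:
        if config.simulate:
            config.sim.seed = config.seed
            dataset, _ = simulate_dataset(config.sim)
        else:
            dataset = load_dataset(config.genotype_path, config.trait_path, config.panel_path)
        gm = dataset.genotypes
        if gm.n == 0:
            raise ValidationError("empty genotype matrix: nothing to analyze")

        stage = "popgen"
        locus_stats = summarize_loci(gm, df_mode=config.hwe_df_mode)

        stage = "ld"
        ld = ld_matrix(gm, tol=config.em_tol, max_iter=config.em_max_iter,
                       n_restarts=config.em_restarts, seed=config.seed)

        stage = "haplotypes"
        hap_full = em_haplotype_frequencies(
            gm, tol=config.em_tol, max_iter=config.em_max_iter,
            n_restarts=config.em_restarts, seed=config.seed,
        )
        hap = filter_haplotypes(hap_full, config.min_hap_freq)

        stage = "diplotypes"
        assignments, class_freqs, retained = assign_diplotypes(
            gm, hap, full_hapset=hap_full, min_class_freq=config.min_class_freq
        )

        stage = "association"
        assoc = AssociationReport()
        if dataset.traits is not None:
            joined = dataset.joined()
            label_by_ind = {a.individual_id: a.class_label for a in assignments}
            joined[DIPLOTYPE_COLUMN] = [label_by_ind.get(i) for i in joined.index]
            assoc = association_report(
                joined,
                markers=gm.locus_ids,
                traits=[t for t in TRAIT_NAMES if t in joined.columns],
                diplotype_column=DIPLOTYPE_COLUMN,
                retained_diplotype_classes=list(retained),
                alpha=config.alpha,
            )
    except CandgeneError as exc:
        raise CandgeneError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return ReportBundle(
        dataset=dataset,
        locus_stats=locus_stats,
        ld=ld,
        haplotypes_full=hap_full,
        haplotypes=hap,
        diplotype_assignments=assignments,
        diplotype_class_freqs=class_freqs,
        retained_classes=retained,
        association=assoc,
        config=config,
    )


def render_locus_stats(rows: list[LocusStats]) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append({
            "locus": r.locus_id,
            "n_refhom": r.genotype_counts[0],
            "n_het": r.genotype_counts[1],
            "n_althom": r.genotype_counts[2],
            "f_refhom": _fmt(r.genotype_freqs[0], 2),
            "f_het": _fmt(r.genotype_freqs[1], 2),
            "f_althom": _fmt(r.genotype_freqs[2], 2),
            "p_ref": _fmt(r.allele_freqs[0], 2),
            "p_alt": _fmt(r.allele_freqs[1], 2),
            "chi2": _fmt(r.chi2, 2),
            "hwe_p": _fmt(r.p_value, 3),
            "het_obs": _fmt(r.het_obs, 3),
            "Ho": _fmt(r.ho, 3),
            "He": _fmt(r.he, 3),
            "Ne": _fmt(r.ne, 3),
            "PIC": _fmt(r.pic, 3),
            "flag": r.error or "",
        })
    return pd.DataFrame(out)


def render_ld(ld: LdMatrixResult) -> pd.DataFrame:
    rows = [{
        "pair": f"{p.locus_a} - {p.locus_b}",
        "D": _fmt(p.d, 3),
        "D_prime": _fmt(p.d_prime, 3),
        "r2": _fmt(p.r2, 3),
        "strong_ld": "yes" if p.strong else "no",
    } for p in ld.pairs]
    rows.append({"pair": "mean", "D": "", "D_prime": _fmt(ld.mean_d_prime, 3),
                 "r2": _fmt(ld.mean_r2, 3), "strong_ld": ""})
    return pd.DataFrame(rows)


def render_haplotypes(hap: HaplotypeSet, loci: list[str]) -> pd.DataFrame:
    order = sorted(range(len(hap.haplotypes)), key=lambda i: -hap.freqs[i])
    rows = []
    for rank, i in enumerate(order, start=1):
        row = {"haplotype": f"Hap{rank}"}
        row.update({l: hap.haplotypes[i][j] for j, l in enumerate(loci)})
        row["freq_percent"] = _fmt(100.0 * hap.freqs[i], 2)
        rows.append(row)
    return pd.DataFrame(rows)


def render_diplotypes(class_freqs: dict[str, float], retained: dict[str, float]) -> pd.DataFrame:
    rows = [{
        "class": lab,
        "frequency": _fmt(f, 3),
        "retained": "yes" if lab in retained else "no",
    } for lab, f in sorted(class_freqs.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows)


def render_association(assoc: AssociationReport) -> pd.DataFrame:
    """Long-format association table (one row per class x trait cell)."""
    rows = []

    def add(result, family):
        for c in result.classes:
            rows.append({
                "family": family,
                "trait": result.trait,
                "class": c.label,
                "n": c.n,
                "raw_mean": _fmt(c.raw_mean, 2),
                "raw_se": _fmt(c.raw_se, 2),
                "lsmean": _fmt(c.lsmean, 2),
                "lsmean_se": _fmt(c.lsmean_se, 2),
                "letters": c.letters,
                "overall_p": _fmt(result.p_value, 3),
            })

    for (marker, _trait), result in sorted(assoc.marker_results.items()):
        add(result, marker)
    for _trait, result in sorted(assoc.diplotype_results.items()):
        add(result, DIPLOTYPE_COLUMN)
    for (family, trait), msg in sorted(assoc.errors.items()):
        rows.append({"family": family, "trait": trait, "class": "", "n": "",
                     "raw_mean": "", "raw_se": "", "lsmean": "", "lsmean_se": "",
                     "letters": "", "overall_p": f"ERROR: {msg}"})
    return pd.DataFrame(rows)


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every rendered table plus the run log; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p

    save("locus_stats", render_locus_stats(bundle.locus_stats))
    save("ld_pairs", render_ld(bundle.ld))
    save("haplotypes", render_haplotypes(bundle.haplotypes, bundle.haplotypes.loci))
    save("haplotypes_full", render_haplotypes(bundle.haplotypes_full, bundle.haplotypes_full.loci))
    save("diplotypes", render_diplotypes(bundle.diplotype_class_freqs, bundle.retained_classes))
    save("association", render_association(bundle.association))

    cfg = bundle.config
    log_lines = [
        f"candgene version: {__version__}",
        f"seed: {cfg.seed}",
        f"hwe_df_mode: {cfg.hwe_df_mode}",
        f"min_hap_freq: {cfg.min_hap_freq}",
        f"min_class_freq: {cfg.min_class_freq}",
        f"alpha: {cfg.alpha}",
        f"em_tol: {cfg.em_tol}",
        f"em_max_iter: {cfg.em_max_iter}",
        f"em_restarts: {cfg.em_restarts}",
        f"n_individuals: {bundle.dataset.genotypes.n}",
        f"n_loci: {bundle.dataset.genotypes.n_loci}",
        f"haplotypes_discarded: {bundle.haplotypes.n_discarded}"
        f" (mass {bundle.haplotypes.discarded_mass:.4f})",
        f"em_converged: {bundle.haplotypes_full.converged}",
        f"em_loglik: {bundle.haplotypes_full.loglik:.6f}",
    ]
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["log"] = log_path
    return paths


def parse_config_file(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file.

    Keys match :class:`PipelineConfig` fields; ``sim.*`` keys address the
    embedded :class:`SimConfig` (e.g. ``sim.n_individuals = 500``).
    Unknown keys raise, to catch typos.
    """
    config = PipelineConfig()
    pipe_fields = {f.name: f.type for f in fields(PipelineConfig)}
    sim_fields = {f.name for f in fields(SimConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"config line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("sim."):
            sub = key[4:]
            if sub not in sim_fields:
                raise ValidationError(f"config line {lineno}: unknown sim key {sub!r}")
            current = getattr(config.sim, sub)
            setattr(config.sim, sub, _coerce(value, current))
        elif key in pipe_fields:
            current = getattr(config, key)
            setattr(config, key, _coerce(value, current))
        else:
            raise ValidationError(f"config line {lineno}: unknown key {key!r}")
    return config


def _coerce(value: str, current):
    if isinstance(current, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(value)
    if isinstance(current, float):
        return float(value)
    if current is None or isinstance(current, str):
        return value
    raise ValidationError(f"cannot set structured field from flat value {value!r}")


__all__ = [
    "PipelineConfig", "ReportBundle", "run_pipeline", "write_report",
    "parse_config_file", "render_locus_stats", "render_ld",
    "render_haplotypes", "render_diplotypes", "render_association",
    "DIPLOTYPE_COLUMN", "write_dataset",
]
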