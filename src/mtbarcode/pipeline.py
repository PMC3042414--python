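"""Orchestration of the four profile evaluations and the consolidated report.

For each profile: K2P distance matrix -> NJ tree -> outgroup rooting ->
species-recovery and cohesive-group statistics; intra/interspecific
variability tables; optional sliding windows for a focal genus (genome
profile), principal-coordinates ordination, substitution-model selection and
saturation profiling on the shared-accession subset.  A stage failure
isolates its profile; the remaining profiles complete and the report marks
the gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import distances, model_fit, ordination, trees, variability
from .profiles import GeneProfile, ProfileSet, translate_profile

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "EvaluationReport", "run_evaluation"]


@dataclass
class PipelineConfig:
    """Declarative configuration of an evaluation run."""

    profiles: list[str] | None = None       # None = all profiles in the set
    outgroup: set[str] = field(default_factory=set)
    window: int = 600
    step: int = 5
    ambiguity_mode: str = "infer"           # for variability tables
    saturation_cap: float = 5.0
    focal_genus: str | None = None
    model_grid: tuple[str, ...] | None = None  # None disables model fitting
    ordination_profiles: list[str] = field(default_factory=list)
    include_singletons: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outgroup" in raw:
            raw["outgroup"] = set(raw["outgroup"])
        if raw.get("model_grid"):
            raw["model_grid"] = tuple(raw["model_grid"])
        return cls(**raw)


@dataclass
class ProfileEvaluation:
    """All computed statistics for one profile."""

    profile: str
    recovery: trees.RecoveryReport | None = None
    variability: variability.VariabilityTable | None = None
    best_model: model_fit.ModelFit | None = None
    gc: float | None = None
    saturation: model_fit.SaturationSeries | None = None
    ordination: ordination.OrdinationResult | None = None
    tree: trees.PhyloTree | None = None
    error: str | None = None


@dataclass
class EvaluationReport:
    """Consolidated per-profile statistics plus cross-profile tests."""

    per_profile: dict[str, ProfileEvaluation]
    windows: list[variability.WindowProfile] = field(default_factory=list)
    anova_intra: tuple | None = None
    anova_inter: tuple | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, ev in self.per_profile.items():
            row = {"profile": name, "error": ev.error}
            if ev.recovery:
                r = ev.recovery
                row.update(
                    species_no=r.species_evaluated,
                    barcode_species=r.barcode_species,
                    recovery_rate=round(r.recovery_rate, 2),
                    genera_no=r.genera_evaluated,
                    cohesive_groups=r.cohesive_groups,
                    cohesive_rate=round(r.cohesive_rate, 2),
                )
            if ev.variability:
                row.update(
                    mean_intra=ev.variability.mean_intra,
                    mean_inter=ev.variability.mean_inter,
                )
            if ev.gc is not None:
                row["gc_percent"] = round(100.0 * ev.gc, 2)
            if ev.best_model:
                row.update(
                    best_model=ev.best_model.model,
                    alpha=ev.best_model.gamma_shape,
                    prop_invariable=ev.best_model.prop_invariable,
                )
            if ev.saturation:
                row["saturation_points"] = len(ev.saturation.pairs)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        for name, ev in self.per_profile.items():
            if ev.tree:
                ev.tree.write_newick(out / f"{name}.nwk")
            if ev.variability:
                ev.variability.to_frame().to_csv(
                    out / f"{name}.variability.tsv", sep="\t", index=False
                )
            if ev.saturation:
                ev.saturation.to_frame().to_csv(
                    out / f"{name}.saturation.tsv", sep="\t", index=False
                )
        for w in self.windows:
            safe = w.taxon_or_pair.replace(" ", "_")
            w.to_frame().to_csv(
                out / f"window.{w.statistic}.{safe}.tsv", sep="\t", index=False
            )


def shared_accessions(pset: ProfileSet, names: list[str]) -> set[str]:
    """Accessions present in every named profile (consistent subsampling)."""
    return set.intersection(*(set(pset[n].alignment) for n in names))


def _evaluate_profile(profile: GeneProfile, config: PipelineConfig,
                      outgroup: set[str]) -> ProfileEvaluation:
    ev = ProfileEvaluation(profile.gene)
    dm = distances.build_distance_matrix(profile, "k2p", "exclude")
    nj = trees.neighbor_joining(dm, config.saturation_cap)
    og = outgroup & set(profile.alignment)
    if not og:
        raise ValueError("no outgroup accession present in profile")
    rooted = trees.root_with_outgroup(nj, og)
    ev.tree = rooted
    ev.recovery = trees.recovery_summary(
        rooted,
        profile.taxonomy,
        outgroup=og,
        profile_name=profile.gene,
        include_singletons=config.include_singletons,
    )
    ingroup = [a for a in profile.alignment if a not in og]
    ev.variability = variability.variability_table(
        profile.subset(ingroup), config.ambiguity_mode
    )
    ev.gc = model_fit.gc_content(profile)
    ev.saturation = model_fit.saturation_profile(profile)
    if config.model_grid:
        fits = model_fit.select_model_bic(profile, rooted, config.model_grid)
        ev.best_model = fits[0] if fits else None
    return ev


def run_evaluation(pset: ProfileSet, config: PipelineConfig) -> EvaluationReport:
    """Run the full evaluation over the configured profiles."""
    names = config.profiles or pset.names()
    outgroup = set(config.outgroup) or set(pset.outgroup_accessions)
    per_profile: dict[str, ProfileEvaluation] = {}
    for name in names:
        try:
            per_profile[name] = _evaluate_profile(pset[name], config, outgroup)
        except Exception as exc:  # noqa: BLE001 - isolate failing profile
            logger.warning("profile %s failed: %s", name, exc)
            per_profile[name] = ProfileEvaluation(name, error=str(exc))

    report = EvaluationReport(per_profile)

    # Cross-profile ANOVA / Tukey on per-taxon means.
    intra_groups = {
        n: list(ev.variability.intra.values())
        for n, ev in per_profile.items()
        if ev.variability and len(ev.variability.intra) >= 2
    }
    inter_groups = {
        n: list(ev.variability.inter.values())
        for n, ev in per_profile.items()
        if ev.variability and len(ev.variability.inter) >= 2
    }
    if len(intra_groups) >= 2:
        report.anova_intra = variability.anova_tukey(intra_groups)
    if len(inter_groups) >= 2:
        report.anova_inter = variability.anova_tukey(inter_groups)

    # Sliding windows for the focal genus on the genome profile.
    if config.focal_genus and "genome" in pset:
        genome = pset["genome"]
        species = sorted({
            t[0] for t in genome.taxonomy.values() if t[1] == config.focal_genus
        })
        counts = {
            sp: sum(1 for t in genome.taxonomy.values() if t[0] == sp)
            for sp in species
        }
        for sp in species:
            if counts[sp] >= 2:
                report.windows.append(
                    variability.sliding_window(
                        genome, sp, config.window, config.step
                    )
                )
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                report.windows.append(
                    variability.sliding_window(
                        genome, (a, b), config.window, config.step
                    )
                )

    # Ordination on the shared-accession subset of the named profiles.
    if config.ordination_profiles:
        shared = shared_accessions(pset, config.ordination_profiles) - outgroup
        for name in config.ordination_profiles:
            ev = per_profile.get(name)
            if ev is None or ev.error:
                continue
            sub = pset[name].subset(sorted(shared))
            dm = distances.build_distance_matrix(sub, "k2p", "exclude")
            groups = {a: sub.taxonomy[a][2] for a in sub.alignment}
            try:
                ev.ordination = ordination.pcoord(dm, dims=3, group_labels=groups)
            except ValueError as exc:
                logger.warning("ordination for %s failed: %s", name, exc)
    return report
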