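"""Bayesian combination of classification and DFE fits, pipeline
orchestration and scoring against synthetic truth.

The headline quantity is the recall P[B0|B]: among mutations that are
beneficial on the current fitness landscape (S > 1), the proportion whose
phylogenetically estimated coefficient S0 also exceeds 1 — i.e. beneficial
mutations that are *non-adaptive*, favoured on the stable ancestral
landscape rather than by recent environmental change. It is obtained by
Bayes' rule from the per-class posteriors P[B|x] (DFE fits) and the
mutation-rate-weighted class priors P[x] (opportunity table).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfe import ClassPosterior, fit_dfe
from .mutsel import CLASS_SYNONYMOUS, SELECTION_CLASSES
from .popgen import (
    OpportunityTable,
    SiteFrequencySpectrum,
    mutational_opportunities,
    ne_estimate,
    subsample_sfs,
    watterson_theta,
)

TRUE_CLASSES = ("D", "N", "B")
_CLASS_OF = dict(zip(SELECTION_CLASSES, TRUE_CLASSES))  # D0 -> D etc.

__all__ = [
    "SelectionReport",
    "marginal_probability",
    "precision_recall",
    "run_pipeline",
    "score_against_truth",
    "DEFAULT_PIPELINE_CONFIG",
]


def marginal_probability(posteriors: dict, opportunities, target: str) -> float:
    """Law of total probability: P[target] = sum_x P[target | x] P[x].

    ``posteriors`` maps the S0 class x to its ClassPosterior; ``opportunities``
    is an OpportunityTable or a {class: P[x]} dict whose priors sum to 1.
    """
    if target not in TRUE_CLASSES:
        raise ValueError(f"target must be one of {TRUE_CLASSES}")
    priors = opportunities.class_priors if isinstance(opportunities, OpportunityTable) else dict(opportunities)
    total = sum(priors.values())
    if not np.isclose(total, 1.0):
        raise ValueError("class priors must sum to 1")
    k = TRUE_CLASSES.index(target)
    return float(sum(posteriors[x].as_array()[k] * priors[x] for x in SELECTION_CLASSES))


def precision_recall(posteriors: dict, opportunities) -> dict:
    """Marginals, precision and recall of the S0 classification.

    precision[x] = P[class(x) | x] is read directly off the posterior;
    recall[y] = P[y0 | y] = P[y | y0] P[y0] / P[y] by Bayes. A recall whose
    marginal P[y] is zero is undefined and flagged (value None).
    """
    priors = opportunities.class_priors if isinstance(opportunities, OpportunityTable) else dict(opportunities)
    marginals = {y: marginal_probability(posteriors, priors, y) for y in TRUE_CLASSES}
    precision = {
        x: float(posteriors[x].as_array()[TRUE_CLASSES.index(_CLASS_OF[x])])
        for x in SELECTION_CLASSES
    }
    recall, recall_defined = {}, {}
    for y in TRUE_CLASSES:
        x0 = y + "0"
        if marginals[y] > 0:
            recall[y] = float(precision[x0] * priors[x0] / marginals[y])
            recall_defined[y] = True
        else:
            recall[y] = None
            recall_defined[y] = False
    return {
        "marginals": marginals,
        "precision": precision,
        "recall": recall,
        "recall_defined": recall_defined,
        "priors": dict(priors),
    }


@dataclass
class SelectionReport:
    """Everything a run estimates, with provenance metadata."""

    opportunities: OpportunityTable
    posteriors: dict                    # S0 class -> ClassPosterior
    marginals: dict                     # P[D], P[N], P[B]
    precision: dict                     # x -> P[class(x) | x]
    recall: dict                        # y -> P[y0 | y] (None if undefined)
    recall_defined: dict
    theta_s: float
    Ne: float
    metadata: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)            # S0 class -> DFEFitResult
    divergence: object = None                           # DivergenceTable | None

    def __post_init__(self):
        for x, post in self.posteriors.items():
            arr = post.as_array()
            assert np.all((arr >= -1e-12) & (arr <= 1 + 1e-12)), x
            assert abs(arr.sum() - 1.0) < 1e-9, x
        assert abs(sum(self.marginals.values()) - 1.0) < 1e-9

    @property
    def p_b0_given_b(self) -> float | None:
        return self.recall["B"]

    def scalars(self) -> dict:
        out = {
            "theta_s": self.theta_s,
            "Ne": self.Ne,
            **{f"P[{y}]": self.marginals[y] for y in TRUE_CLASSES},
            **{f"P[{_CLASS_OF[x]}|{x}]": self.precision[x] for x in SELECTION_CLASSES},
            **{f"P[{y}0|{y}]": self.recall[y] for y in TRUE_CLASSES},
            **{f"P[{x}]": self.opportunities.P(x) for x in SELECTION_CLASSES},
            "L_tot": self.opportunities.L_tot,
            "L_syn": self.opportunities.L_syn,
            **{f"L[{x}]": self.opportunities.L(x) for x in SELECTION_CLASSES},
        }
        if self.divergence is not None:
            out["dS"] = self.divergence.dS
            out["delta_dnds"] = self.divergence.delta
        return out

    def to_dict(self) -> dict:
        return {
            "scalars": self.scalars(),
            "posteriors": {
                x: dict(zip(("P[D|x]", "P[N|x]", "P[B|x]"), map(float, self.posteriors[x].as_array())))
                for x in SELECTION_CLASSES
            },
            "recall_defined": self.recall_defined,
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# scalars\n")
            for k, v in self.scalars().items():
                fh.write(f"{k}\t{v}\n")
            fh.write("\n# posteriors\nclass\tP[D|x]\tP[N|x]\tP[B|x]\n")
            for x in SELECTION_CLASSES:
                arr = self.posteriors[x].as_array()
                fh.write(f"{x}\t{arr[0]!r}\t{arr[1]!r}\t{arr[2]!r}\n")
            fh.write("\n# metadata\n")
            for k in sorted(self.metadata):
                fh.write(f"{k}\t{self.metadata[k]}\n")


# -- pipeline ---------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "mode": "synthetic",
    "seed": 0,
    "classification": "true",      # "true" (generator landscape) | "estimated"
    "subsample": None,             # target chromosome count, or None
    "cpg_filter": False,
    "with_divergence": False,
    "divergence_in_likelihood": False,
    "dfe_form": "parametric",
    "fit_epsilon": False,
    "n_starts": 8,
    "out_dir": None,
}


def run_pipeline(config: dict) -> SelectionReport:
    """Profiles -> classification -> opportunities -> SFS -> DFE -> report.

    ``config`` (flat key-value; see DEFAULT_PIPELINE_CONFIG) either describes
    a synthetic bundle (mode "synthetic", bundle keys passed through to the
    generator) or names input files (mode "data": snps_file plus either
    profiles_file or alignment_fasta + tree_newick). Deterministic given the
    seed; intermediates are written when out_dir is set.
    """
    from .synthetic import DEFAULT_BUNDLE_CONFIG

    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    try:
        if cfg["mode"] == "synthetic":
            return _run_synthetic(cfg, seed)
        if cfg["mode"] == "data":
            return _run_data(cfg, seed)
        raise ValueError(f"unknown pipeline mode {cfg['mode']!r}")
    except Exception as exc:
        if not getattr(exc, "_stage_tagged", False):
            exc._stage_tagged = True
            exc.args = (f"[pipeline mode={cfg.get('mode')}] {exc}",) + exc.args[1:]
        raise


def _stage(name):
    """Context manager tagging exceptions with the failing pipeline stage."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except Exception as exc:
            exc._stage_tagged = True
            exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
            raise

    return cm()


def _run_synthetic(cfg: dict, seed: int) -> SelectionReport:
    from .synthetic import DEFAULT_BUNDLE_CONFIG, make_scenario_bundle

    bundle_cfg = {k: cfg[k] for k in DEFAULT_BUNDLE_CONFIG if k in cfg}
    with _stage("simulate"):
        bundle = make_scenario_bundle(bundle_cfg, seed=seed)
    sc = bundle.scenario

    with _stage("profiles"):
        if cfg["classification"] == "true":
            Fmat = sc.Fmat
            profiles = sc.profiles
        elif cfg["classification"] == "estimated":
            from .mutsel import profiles_to_matrix
            from .phylo import estimate_site_profiles

            profiles = estimate_site_profiles(bundle.alignment, sc.tree, sc.mu, seed=seed)
            Fmat = profiles_to_matrix(profiles)
        else:
            raise ValueError("classification must be 'true' or 'estimated'")

    with _stage("opportunities"):
        exclude = bundle.cpg_mask if (cfg["cpg_filter"] and bundle.cpg_mask is not None) else None
        opp = mutational_opportunities(bundle.extant_exome, sc.mu, Fmat, exclude_sites=exclude)

    with _stage("sfs"):
        if bundle.snps is not None and cfg["classification"] == "estimated":
            from .popgen import build_sfs

            sfs = build_sfs(bundle.snps, opp, Fmat, exclude_cpg=cfg["cpg_filter"])
        else:
            # aggregate-mode spectra (or detail spectra classified on the
            # same landscape the simulator already used)
            sfs = dict(bundle.class_sfs)
            if cfg["cpg_filter"]:
                raise ValueError("cpg_filter requires per-SNP records and estimated/true detail SFS")
        sfs = _attach_opportunities(sfs, opp)
        if cfg["subsample"]:
            m = int(cfg["subsample"])
            sfs = {lab: subsample_sfs(s, m) for lab, s in sfs.items()}

    divergence_table, div_pairs = None, {}
    if cfg["with_divergence"]:
        with _stage("divergence"):
            from .divergence import dnds_by_class, map_substitutions, reconstruct_branch_base
            from .popgen import AncestralExome

            rec = reconstruct_branch_base(bundle.alignment, sc.tree, sc.mu)
            seg = bundle.snps.table["site"].to_numpy() if bundle.snps is not None else []
            subs = map_substitutions(rec, AncestralExome(bundle.extant_exome), Fmat, segregating_sites=seg)
            if len(subs.excluded_multi_step):
                opp_div = mutational_opportunities(
                    bundle.extant_exome, sc.mu, Fmat, exclude_sites=subs.excluded_multi_step
                )
            else:
                opp_div = opp
            divergence_table = dnds_by_class(subs, opp_div)
            if cfg["divergence_in_likelihood"]:
                for x in SELECTION_CLASSES:
                    div_pairs[x] = (
                        (divergence_table.D[x], divergence_table.L[x]),
                        (divergence_table.D_syn, divergence_table.L_syn),
                    )

    report = _fit_and_report(sfs, opp, cfg, seed, divergence_table, div_pairs)
    report.metadata.update(
        {
            "mode": "synthetic",
            "theta_true": sc.theta,
            "shift_fraction": sc.shift_fraction,
            "n_sites": sc.n_sites,
        }
    )
    if cfg["out_dir"]:
        _write_intermediates(cfg["out_dir"], report, sfs, profiles, bundle=bundle)
    return report


def _run_data(cfg: dict, seed: int) -> SelectionReport:
    from . import io as mio
    from .mutation import NucleotideMutationModel
    from .mutsel import profiles_to_matrix
    from .popgen import PolymorphismSet, build_sfs, reconstruct_ancestral_exome
    from .phylo import CodonAlignment, Phylogeny

    mu = cfg.get("mu")
    if mu is None:
        kappa = float(cfg.get("kappa", 2.0))
        freqs = cfg.get("base_freqs", (0.25, 0.25, 0.25, 0.25))
        mu = NucleotideMutationModel.hky(kappa, freqs)
    with _stage("inputs"):
        snps = PolymorphismSet.from_tsv(cfg["snps_file"])
        if "profiles_file" in cfg:
            profiles = mio.read_profiles(cfg["profiles_file"])
            alignment = tree = None
            if "alignment_fasta" in cfg:
                alignment = CodonAlignment.from_fasta(cfg["alignment_fasta"])
        else:
            alignment = CodonAlignment.from_fasta(cfg["alignment_fasta"])
            tree = Phylogeny.from_newick(open(cfg["tree_newick"]).read())
            from .phylo import estimate_site_profiles

            with _stage("profiles"):
                profiles = estimate_site_profiles(alignment, tree, mu, seed=seed)
        Fmat = profiles_to_matrix(profiles)
        if alignment is not None:
            focal = cfg.get("focal_label", "focal")
            reference = alignment.codons[alignment.taxa.index(focal)]
        else:
            reference = np.asarray(cfg["reference_codons"], dtype=np.int64)
    with _stage("opportunities"):
        exome = reconstruct_ancestral_exome(reference, snps)
        opp = mutational_opportunities(exome, mu, Fmat)
    with _stage("sfs"):
        sfs = build_sfs(snps, opp, Fmat, exclude_cpg=cfg["cpg_filter"])
        sfs = _attach_opportunities(sfs, opp)
        if cfg["subsample"]:
            sfs = {lab: subsample_sfs(s, int(cfg["subsample"])) for lab, s in sfs.items()}
    report = _fit_and_report(sfs, opp, cfg, seed, None, {})
    report.metadata["mode"] = "data"
    if cfg["out_dir"]:
        _write_intermediates(cfg["out_dir"], report, sfs, profiles)
    return report


def _attach_opportunities(sfs: dict, opp: OpportunityTable) -> dict:
    out = {}
    for lab, s in sfs.items():
        L = opp.L_syn if lab == CLASS_SYNONYMOUS else opp.L(lab)
        out[lab] = SiteFrequencySpectrum(counts=s.counts, n=s.n, L=L, label=lab)
    return out


def _fit_and_report(sfs, opp, cfg, seed, divergence_table, div_pairs) -> SelectionReport:
    with _stage("theta"):
        theta_s = watterson_theta(sfs[CLASS_SYNONYMOUS])
        Ne = ne_estimate(theta_s, float(cfg.get("u", 7.24e-9)))
    fits, posteriors = {}, {}
    with _stage("dfe"):
        for k, x in enumerate(SELECTION_CLASSES):
            fits[x] = fit_dfe(
                sfs[x],
                sfs[CLASS_SYNONYMOUS],
                divergence=div_pairs.get(x),
                form=cfg["dfe_form"],
                fit_epsilon=cfg["fit_epsilon"],
                n_starts=int(cfg["n_starts"]),
                seed=seed * 1000 + k,
            )
            posteriors[x] = fits[x].class_posterior
    with _stage("report"):
        pr = precision_recall(posteriors, opp)
        report = SelectionReport(
            opportunities=opp,
            posteriors=posteriors,
            marginals=pr["marginals"],
            precision=pr["precision"],
            recall=pr["recall"],
            recall_defined=pr["recall_defined"],
            theta_s=theta_s,
            Ne=Ne,
            metadata={
                "seed": seed,
                "dfe_form": cfg["dfe_form"],
                "fit_epsilon": cfg["fit_epsilon"],
                "cpg_filter": cfg["cpg_filter"],
                "with_divergence": cfg["with_divergence"],
                "subsample": cfg["subsample"],
                "classification": cfg.get("classification", "n/a"),
                "converged": all(f.converged for f in fits.values()),
            },
            fits=fits,
            divergence=divergence_table,
        )
    return report


def _write_intermediates(out_dir, report, sfs, profiles, bundle=None) -> None:
    import os

    from . import io as mio

    os.makedirs(out_dir, exist_ok=True)
    mio.write_profiles(profiles, os.path.join(out_dir, "profiles.tsv"))
    mio.write_sfs(sfs, os.path.join(out_dir, "sfs.tsv"))
    for x, fit in report.fits.items():
        mio.write_dfe_fit(fit, os.path.join(out_dir, f"dfe_{x}.txt"))
    if report.divergence is not None:
        report.divergence.to_tsv(os.path.join(out_dir, "divergence.tsv"))
    if bundle is not None and bundle.snps is not None:
        bundle.snps.to_tsv(os.path.join(out_dir, "snps.tsv"))
    report.to_tsv(os.path.join(out_dir, "report.tsv"))
    report.to_json(os.path.join(out_dir, "report.json"))


# -- scoring ----------------------------------------------------------------

def score_against_truth(report: SelectionReport, truth) -> dict:
    """Absolute errors of the report against exact generative oracles.

    Oracles come from the GroundTruth joint mass table (mu-weighted over
    every possible mutation). theta error is included when the run metadata
    carries the generative theta.
    """
    if truth is None:
        raise ValueError("ground truth is required for scoring")
    out = {"posterior_abs_error": {}, "recall_abs_error": {}}
    for x in SELECTION_CLASSES:
        est = report.posteriors[x].as_array()
        oracle = np.array([truth.oracle_posterior(x, t) for t in TRUE_CLASSES])
        out["posterior_abs_error"][x] = float(np.nanmax(np.abs(est - oracle)))
    for y in TRUE_CLASSES:
        oracle = truth.oracle_recall(y)
        est = report.recall[y]
        out["recall_abs_error"][y] = (
            float(abs(est - oracle)) if (est is not None and np.isfinite(oracle)) else None
        )
    out["p_b0_given_b"] = report.p_b0_given_b
    out["p_b0_given_b_oracle"] = truth.oracle_recall("B")
    if "theta_true" in report.metadata:
        out["theta_abs_error"] = float(abs(report.theta_s - report.metadata["theta_true"]))
    return out
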