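"""Plain-text serialization for pipeline artifacts.

All formats are TSV or flat key-value text so runs are diffable and
greppable. SNP tables are handled by ``PolymorphismSet.to_tsv/from_tsv``.
"""
from __future__ import annotations

import ast

import numpy as np
import pandas as pd

from ._codes import AMINO_ACIDS
from .dfe import DFEFitResult, DFEModel, DiscreteDFE
from .mutsel import SELECTION_CLASSES, SiteFitnessProfile
from .popgen import OpportunityTable, SiteFrequencySpectrum

__all__ = [
    "write_profiles",
    "read_profiles",
    "write_sfs",
    "read_sfs",
    "read_config",
    "write_config",
    "write_dfe_fit",
    "read_dfe_fit",
    "write_opportunities",
    "read_opportunities",
]


# -- fitness profiles -------------------------------------------------------

def write_profiles(profiles, path) -> None:
    """Site-by-amino-acid fitness TSV: `site` plus 20 alphabetical aa columns."""
    rows = []
    for p in profiles:
        rows.append({"site": p.site, **{aa: p.F[i] for i, aa in enumerate(AMINO_ACIDS)}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profiles(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = [aa for aa in AMINO_ACIDS if aa not in df.columns]
    if missing or "site" not in df.columns:
        raise ValueError(f"profile table missing columns: {['site'] * ('site' not in df.columns) + missing}")
    F = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    return [SiteFitnessProfile(site=int(s), F=F[k]) for k, s in enumerate(df["site"])]


# -- site frequency spectra -------------------------------------------------

def write_sfs(spectra, path) -> None:
    """One line per spectrum: label, n, L, then xi_1..xi_{n-1} (tab-separated)."""
    if isinstance(spectra, dict):
        spectra = list(spectra.values())
    with open(path, "w") as fh:
        fh.write("# label\tn\tL\txi_1..xi_{n-1}\n")
        for s in spectra:
            xi = "\t".join(f"{v:.10g}" for v in s.counts)
            fh.write(f"{s.label}\t{s.n}\t{s.L:.10g}\t{xi}\n")


def read_sfs(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            label, n, L = parts[0], int(parts[1]), float(parts[2])
            counts = np.array([float(v) for v in parts[3:]])
            out[label] = SiteFrequencySpectrum(counts=counts, n=n, L=L, label=label)
    return out


# -- opportunity tables -----------------------------------------------------

def write_opportunities(opp: OpportunityTable, path) -> None:
    kv = {
        "L_tot": opp.L_tot,
        "mu_tot": opp.mu_tot,
        "mu_syn": opp.mu_syn,
        "dropped_stop_weight": opp.dropped_stop_weight,
        **{f"mu_{x}": opp.mu_x[x] for x in SELECTION_CLASSES},
    }
    write_config(kv, path)


def read_opportunities(path) -> OpportunityTable:
    kv = read_config(path)
    return OpportunityTable(
        L_tot=float(kv["L_tot"]),
        mu_tot=float(kv["mu_tot"]),
        mu_syn=float(kv["mu_syn"]),
        mu_x={x: float(kv[f"mu_{x}"]) for x in SELECTION_CLASSES},
        dropped_stop_weight=float(kv.get("dropped_stop_weight", 0.0)),
    )


# -- flat key-value configs and fit summaries -------------------------------

def _parse_value(text: str):
    text = text.strip()
    try:
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def read_config(path) -> dict:
    """Flat `key = value` lines; values parsed as Python literals when possible."""
    cfg = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            cfg[key.strip()] = _parse_value(value)
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(cfg):
            fh.write(f"{key} = {cfg[key]!r}\n")


def write_dfe_fit(fit: DFEFitResult, path) -> None:
    """Fitted DFE as flat key-value text with a convergence block."""
    lines = []
    m = fit.model
    if isinstance(m, DFEModel):
        lines += [
            "form = parametric",
            f"beta_d = {m.beta_d!r}",
            f"b = {m.b!r}",
            f"p_b = {m.p_b!r}",
            f"beta_b = {m.beta_b!r}",
            f"epsilon = {m.epsilon!r}",
        ]
    elif isinstance(m, DiscreteDFE):
        lines += [
            "form = discrete",
            f"edges = {tuple(float(e) for e in m.edges)!r}",
            f"masses = {tuple(float(v) for v in m.masses)!r}",
            f"epsilon = {m.epsilon!r}",
        ]
    else:
        raise TypeError(f"cannot serialize model type {type(m)!r}")
    lines += [
        f"theta = {fit.theta!r}",
        "# convergence",
        f"loglik = {fit.loglik!r}",
        f"converged = {fit.converged!r}",
        f"degenerate = {fit.degenerate!r}",
        f"n_starts = {len(fit.starts)!r}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dfe_fit(path) -> DFEFitResult:
    kv = read_config(path)
    if kv["form"] == "parametric":
        model = DFEModel(
            beta_d=kv["beta_d"], b=kv["b"], p_b=kv["p_b"], beta_b=kv["beta_b"],
            epsilon=kv.get("epsilon") or 0.0,
        )
    elif kv["form"] == "discrete":
        model = DiscreteDFE(
            edges=np.array(kv["edges"]), masses=np.array(kv["masses"]),
            epsilon=kv.get("epsilon") or 0.0,
        )
    else:
        raise ValueError(f"unknown DFE form {kv['form']!r}")
    return DFEFitResult(
        model=model, loglik=float(kv["loglik"]), theta=float(kv["theta"]),
        converged=bool(kv["converged"]), degenerate=bool(kv["degenerate"]),
    )
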