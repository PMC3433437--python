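"""End-to-end orchestration: reconstruct -> map -> switches -> coevolution -> null.

A pipeline run consumes either real inputs (alignment + tree + structure) or a
generated benchmark, and writes the three headline tables — coevolving pairs,
switch records with TIR, and the paired-difference test — plus a manifest that
suffices to reproduce the run exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestor, coevostat, compswitch, evomodel, rnasim, seqdata
from .seqdata import RnacoevoError

logger = logging.getLogger("rnacoevo")


class ConfigError(RnacoevoError):
    pass


class StageError(RnacoevoError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration; every CLI flag has a twin here."""

    alignment: str | None = None
    tree: str | None = None
    structure: str | None = None
    benchmark: dict | None = None   # mode, n_taxa, depth, selection_strength, n_coevolving
    model: dict | None = None       # GTR+G parameter block; None = package default
    fit_model: bool = False
    alpha: float = 0.05
    posterior_cutoff: float = 0.7
    wobble_ok: bool = True
    max_gap_fraction: float = 0.5
    n_bootstrap: int = 500
    n_permutations: int = 500
    n_neutral_replicates: int = 10
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        has_inputs = all(x is not None for x in (self.alignment, self.tree, self.structure))
        if not has_inputs and self.benchmark is None:
            raise ConfigError("config needs input paths or a benchmark block")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if not (0 <= self.posterior_cutoff <= 1):
            raise ConfigError("posterior_cutoff must be in [0, 1]")
        if self.n_bootstrap < 100:
            raise ConfigError("n_bootstrap must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    summary: dict
    records: list = field(default_factory=list)


def _load_inputs(cfg: PipelineConfig, rng: np.random.Generator):
    if cfg.benchmark is not None:
        b = dict(cfg.benchmark)
        mode = b.pop("mode", "paired")
        sim_cfg = rnasim.SimConfig(
            n_taxa=int(b.pop("n_taxa", 100)),
            depth=float(b.pop("depth", 0.5)),
            selection_strength=float(b.pop("selection_strength", 1.0)),
            n_coevolving=b.pop("n_coevolving", None),
            model=_build_model(cfg),
            seed=int(rng.integers(2 ** 31 - 1)))
        if b:
            raise ConfigError(f"unknown benchmark keys: {sorted(b)}")
        sim = rnasim.generate_benchmark(sim_cfg, mode=mode)
        return sim.alignment, sim.tree, sim.structure, sim
    aln = seqdata.read_alignment(cfg.alignment)
    tree = seqdata.read_tree(cfg.tree)
    ss = seqdata.read_structure(cfg.structure)
    return aln, tree, ss, None


def _build_model(cfg: PipelineConfig) -> evomodel.GtrGammaModel:
    if cfg.model is not None:
        return evomodel.GtrGammaModel.from_config(cfg.model)
    return evomodel.GtrGammaModel()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    rng = np.random.default_rng(cfg.seed)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": cfg.seed}

    aln, tree, ss, sim = _stage("inputs")(_load_inputs)(cfg, rng)
    model = _build_model(cfg)
    if cfg.fit_model and sim is None:
        model = _stage("fit_model")(evomodel.fit_model)(aln, tree)
    summary["n_taxa"] = aln.n_taxa
    summary["n_sites"] = aln.n_sites

    recon = _stage("reconstruction")(ancestor.reconstruct_ancestors)(aln, tree, model)
    smap = _stage("substitution_mapping")(ancestor.map_substitutions)(recon, aln, tree)
    summary["mean_map_posterior"] = recon.mean_map_posterior

    @_stage("switches")
    def _switches():
        records = compswitch.detect_switches(recon, aln, tree, ss,
                                             posterior_cutoff=cfg.posterior_cutoff)
        tir = compswitch.compute_tir(records)
        pdt = compswitch.paired_difference_test(recon, aln, tree, ss)
        states = ancestor.node_state_matrix(recon, aln, tree)
        traj = compswitch.stem_integrity_trajectory(states, ss, tree,
                                                    wobble_ok=cfg.wobble_ok)
        mech = compswitch.classify_compensation_mechanisms(states, tree, ss)
        return records, tir, pdt, traj, mech

    records, tir, pdt, traj, mech = _switches()
    tables["switch_records"] = compswitch.records_to_table(records)
    tables["tir_summary"] = tir.summary()
    tables["tir_breakdown"] = tir.breakdown
    tables["paired_difference"] = pd.DataFrame([pdt.to_row()])
    tables["stem_integrity"] = traj
    tables["compensation_mechanisms"] = mech
    summary.update({
        "n_switches": tir.n_switches, "n_terminal": tir.n_terminal,
        "n_intermediate": tir.n_intermediate, "n_multiple": tir.n_multiple,
        "tir": tir.tir, "paired_diff_chi2": pdt.chi2,
        "paired_diff_p": pdt.p_value,
    })

    @_stage("coevolution")
    def _coevolution():
        sites = aln.ungapped_sites(cfg.max_gap_fraction)
        variable = [int(s) for s in sites
                    if len(set(aln.column(s)[aln.column(s) >= 0])) > 1]
        scores = coevostat.mip_matrix(aln, variable,
                                      n_permutations=cfg.n_permutations,
                                      seed=int(rng.integers(2 ** 31 - 1)))
        null = coevostat.parametric_bootstrap_null(
            tree, model, aln.n_sites, n_replicates=cfg.n_bootstrap,
            seed=int(rng.integers(2 ** 31 - 1)))
        coevostat.attach_vector_pvalues(scores, smap, null)
        return scores

    scores = _coevolution()
    tables["coevolution_scores"] = coevostat.scores_to_table(scores, ss)
    consensus = coevostat.consensus_pairs(scores, cfg.alpha, ss)
    tables["consensus_pairs"] = consensus
    summary["n_consensus_pairs"] = int(len(consensus))

    @_stage("neutral_null")
    def _neutral_null():
        rows = []
        pooled_t = pooled_i = pooled_p = pooled_u = 0
        for rep in range(cfg.n_neutral_replicates):
            s = int(rng.integers(2 ** 31 - 1))
            nsim = rnasim.simulate_neutral(tree, model, aln.n_sites, s)
            nrecon = ancestor.reconstruct_ancestors(nsim.alignment, tree, model)
            nrec = compswitch.detect_switches(nrecon, nsim.alignment, tree, ss,
                                              posterior_cutoff=cfg.posterior_cutoff)
            ntir = compswitch.compute_tir(nrec)
            npdt = compswitch.paired_difference_test(nrecon, nsim.alignment, tree, ss)
            pooled_t += ntir.n_terminal
            pooled_i += ntir.n_intermediate
            pooled_p += npdt.observed_paired
            pooled_u += npdt.observed_unpaired
            rows.append({"replicate": rep, "n_terminal": ntir.n_terminal,
                         "n_intermediate": ntir.n_intermediate,
                         "tir": ntir.tir if not ntir.undefined else np.nan,
                         "paired": npdt.observed_paired,
                         "unpaired": npdt.observed_unpaired})
        df = pd.DataFrame(rows)
        pooled_tir = pooled_t / pooled_i if pooled_i else np.nan
        frac = pooled_p / (pooled_p + pooled_u) if (pooled_p + pooled_u) else np.nan
        return df, pooled_tir, frac

    if cfg.n_neutral_replicates > 0:
        ndf, pooled_tir, neutral_frac = _neutral_null()
        tables["neutral_null"] = ndf
        summary["neutral_tir"] = pooled_tir
        summary["neutral_paired_fraction"] = neutral_frac
        finite = ndf["tir"].dropna()
        if len(finite):
            summary["neutral_tir_q95"] = float(np.quantile(finite, 0.95))
            summary["tir_exceeds_neutral_q95"] = bool(
                tir.tir > summary["neutral_tir_q95"])

    return PipelineResult(tables, summary, records)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(result: PipelineResult, cfg: PipelineConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        seqdata.write_table(df, out / f"{name}.tsv")
    manifest = {
        "config": asdict(cfg),
        "versions": _versions(),
        "summary": _plain(result.summary),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(format_summary(result.summary))


def format_summary(s: dict) -> str:
    lines = ["rnacoevo run summary", "====================", ""]
    for key in sorted(s):
        lines.append(f"{key}: {s[key]}")
    lines.append("")
    return "\n".join(lines)


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, float) and not np.isfinite(v):
            v = str(v)
        out[k] = v
    return out


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"rnacoevo": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
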