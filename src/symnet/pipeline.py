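"""Full-pipeline orchestration: screen -> estimate per group -> metrics ->
communities -> stability -> comparison, with a JSON run report."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .communities import CommunityPartition, core_symptom_cluster, walktrap
from .comparison import nct, subsample_to_match
from .core_data import BinarySymptomMatrix, filter_symptoms, load_matrix, occurrence_table
from .ising import estimate_ising, global_strength, spearman_density, write_network
from .metrics import compute_centrality, core_symptom
from .resampling import (
    DEFAULT_DROP_PROPORTIONS,
    bootstrap_edges,
    case_drop_bootstrap,
    cs_coefficient,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one full run; every seed is explicit."""

    input_path: str
    group_column: str = "group"
    groups: tuple[str, str] = ("lt6m", "6to12m")
    screen_lo: float = 0.01
    screen_hi: float = 0.99
    gamma: float = 0.25
    walktrap_t: int = 4
    b_edges: int = 1000
    b_casedrop: int = 250
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    n_perm: int = 1000
    subsample: bool = True
    seed_bootstrap: int = 1
    seed_casedrop: int = 2
    seed_subsample: int = 3
    seed_nct: int = 4
    out_dir: str = "symnet_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.groups = tuple(cfg.groups)
        cfg.drop_proportions = tuple(cfg.drop_proportions)
        return cfg


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report["stages"].append({"stage": name, "seconds": round(dt, 3),
                                     "ok": exc is None})
            logger.info("stage %s: %.2fs ok=%s", name, dt, exc is None)
            if exc is not None:
                raise PipelineError(name, exc) from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig, matrix: BinarySymptomMatrix | None = None) -> dict:
    """Run the whole analysis and write the report bundle to ``out_dir``.

    ``matrix`` may be passed directly (e.g. from a generator); otherwise
    ``config.input_path`` is loaded.  Returns the run report dict, which is
    also written as ``report.json``.  On stage failure the partial outputs
    are retained next to a ``FAILED`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "symnet_version": __version__,
        "config": {**asdict(config),
                   "groups": list(config.groups),
                   "drop_proportions": list(config.drop_proportions)},
        "stages": [],
        "groups": {},
    }
    try:
        with _stage(report, "load"):
            m = matrix if matrix is not None else load_matrix(
                config.input_path, config.group_column
            )
            labels = m.group_labels()
            for g in config.groups:
                if g not in labels:
                    raise ValueError(f"group label {g!r} not present in data")
            n_by_group = {g: m.select_group(g).n_cases for g in config.groups}
            report["n_by_group"] = n_by_group
            report["n_total"] = int(sum(n_by_group.values()))
            report["p_symptoms_input"] = m.p_symptoms

        with _stage(report, "screen"):
            screened, excluded = filter_symptoms(m, config.screen_lo, config.screen_hi)
            report["excluded_symptoms"] = excluded
            report["p_symptoms_retained"] = screened.p_symptoms

        with _stage(report, "occurrence"):
            occ = occurrence_table(screened)
            occ.to_csv(out / "occurrence.tsv", sep="\t", index=False)

        per_group: dict[str, dict] = {}
        for g in config.groups:
            sub = screened.select_group(g)
            gdir = out / g
            gdir.mkdir(exist_ok=True)
            info: dict = {"n_cases": sub.n_cases}

            with _stage(report, f"estimate[{g}]"):
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    net = estimate_ising(sub, gamma=config.gamma)
                info["warnings"] = [str(w.message) for w in wlist]
                write_network(net, gdir / "edges.tsv", gdir / "thresholds.tsv")
                info["edge_count"] = net.edge_count()
                info["global_strength"] = global_strength(net)
                info["density_sum_spearman"] = spearman_density(sub)

            with _stage(report, f"metrics[{g}]"):
                cent = compute_centrality(net)
                cent.to_csv(gdir / "centrality.tsv", sep="\t", index=False)
                info["core_symptom"] = core_symptom(cent)

            with _stage(report, f"communities[{g}]"):
                part = walktrap(net, t=config.walktrap_t)
                part.core_cluster = core_symptom_cluster(part, cent)
                info["core_cluster"] = part.core_cluster
                info["n_clusters"] = part.n_clusters
                info["modularity"] = part.modularity
                members = pd.DataFrame(
                    {
                        "code": list(net.catalog.codes),
                        "name": list(net.catalog.names),
                        "cluster": [part.assignment[c] for c in net.catalog.codes],
                        "is_core_cluster": [
                            part.assignment[c] == part.core_cluster
                            for c in net.catalog.codes
                        ],
                    }
                )
                members.to_csv(gdir / "communities.tsv", sep="\t", index=False)
                with open(gdir / "merges.json", "w") as fh:
                    json.dump({"merges": part.merges,
                               "modularity": part.modularity}, fh, indent=1)

            with _stage(report, f"stability[{g}]"):
                eb = bootstrap_edges(
                    sub, B=config.b_edges, seed=config.seed_bootstrap,
                    gamma=config.gamma,
                )
                eb.summary().to_csv(gdir / "edge_bootstrap.tsv", sep="\t", index=False)
                cd = case_drop_bootstrap(
                    sub,
                    proportions=config.drop_proportions,
                    B=config.b_casedrop,
                    seed=config.seed_casedrop,
                    gamma=config.gamma,
                )
                cs = cs_coefficient(cd)
                info["cs_coefficient"] = cs
                info["bootstrap_failed_replicates"] = eb.n_failed
                info["casedrop_skipped"] = cd.n_skipped

            per_group[g] = info
            report["groups"][g] = info

        with _stage(report, "compare"):
            ga = screened.select_group(config.groups[0])
            gb = screened.select_group(config.groups[1])
            rec = None
            if config.subsample:
                ga, gb, rec = subsample_to_match(ga, gb, seed=config.seed_subsample)
            res = nct(ga, gb, n_perm=config.n_perm, seed=config.seed_nct,
                      gamma=config.gamma, subsample_record=rec)
            res.edge_table.to_csv(out / "nct_edges.tsv", sep="\t", index=False)
            report["comparison"] = {
                "m_observed": res.m_observed,
                "s_observed": res.s_observed,
                "p_structure": res.p_structure,
                "p_strength": res.p_strength,
                "n_perm": res.n_perm,
                "subsample": rec,
            }
    except PipelineError:
        (out / "FAILED").write_text(json.dumps(report["stages"], indent=1))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
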