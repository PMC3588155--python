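"""One-command end-to-end pipeline.

simulate → pairwise screen → network → clustering → classification →
survival, with a manifest (seed, config hash, versions) and a small HTML
report.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import pairwise_screen
from .classify import classify_cohort
from .clustering import cluster
from .cohort import CORE_MARKERS, Cohort, read_cohort, write_cohort
from .network import annotate_signs, find_loops, learn_dag
from .simulate import GeneratorConfig, SurvivalConfig, simulate_cohort
from .survival import group_survival_analysis, km_estimate

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_STAGES = ("simulate", "associate", "network", "cluster", "classify", "survive")


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 7
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in _STAGES})
    q_threshold: float = 0.05
    ess: float = 1.0
    max_parents: int = 4
    metric: str = "hamming"
    linkage: str = "average"
    cohort_path: str | None = None      # skip simulation, load this TSV

    def config_hash(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        d = dataclasses.asdict(self)
        d.pop("outdir", None)       # output location is not scientific config
        payload = json.dumps(clean(d), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration (keys mirror PipelineConfig)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen = raw.pop("generator", {})
    surv = gen.pop("survival", {}) if isinstance(gen, dict) else {}
    edges = gen.pop("edges", None)
    gcfg = GeneratorConfig(**gen) if gen or surv or edges else GeneratorConfig()
    if edges:
        gcfg.edges = {tuple(k.split("-")): float(v) for k, v in edges.items()}
    if surv:
        gcfg.survival = SurvivalConfig(**surv)
    return PipelineConfig(generator=gcfg, **raw)


def _log(msg: str) -> None:
    print(f"[crcmolclass] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest.

    Any stage failure halts with the stage name; partial outputs are left in
    place for inspection.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_run": [],
        "outputs": {},
    }
    cohort: Cohort | None = None
    stage = "simulate"
    try:
        if config.cohort_path:
            cohort, _ = read_cohort(config.cohort_path)
        elif config.stages.get("simulate", True):
            _log(f"simulate: n={config.generator.n} seed={config.seed}")
            cohort = simulate_cohort(config.generator, seed=config.seed)
            write_cohort(cohort, out / "cohort.tsv")
            manifest["outputs"]["cohort"] = "cohort.tsv"
            manifest["stages_run"].append("simulate")
        if cohort is None:
            raise RuntimeError("no cohort: enable simulate or give cohort_path")

        stage = "classify"
        if config.stages.get("classify", True):
            _log("classify: assigning molecular groups")
            cohort, summary = classify_cohort(cohort)
            write_cohort(cohort, out / "classified.tsv")
            (out / "summary.json").write_text(json.dumps({
                "counts": summary.counts,
                "coverage_groups_1_to_5": summary.coverage_groups_1_to_5,
            }, indent=2, sort_keys=True))
            manifest["outputs"]["classified"] = "classified.tsv"
            manifest["stages_run"].append("classify")

        stage = "associate"
        if config.stages.get("associate", True):
            _log("associate: pairwise molecular screen")
            res = pairwise_screen(cohort, list(CORE_MARKERS),
                                  q_threshold=config.q_threshold)
            rows = [{
                "factor1": r.factors[0], "factor2": r.factors[1],
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p": r.p, "q": r.q, "sign": r.sign,
            } for r in res]
            pd.DataFrame(rows).to_csv(out / "assoc.tsv", sep="\t", index=False,
                                      na_rep="NA")
            manifest["outputs"]["assoc"] = "assoc.tsv"
            manifest["stages_run"].append("associate")

        stage = "network"
        if config.stages.get("network", True):
            _log("network: exact DAG search")
            m = cohort.core_marker_matrix()
            dag = learn_dag(m, ess=config.ess, max_parents=config.max_parents)
            skel = annotate_signs(dag, m)
            loops = find_loops(skel)
            net = {
                "nodes": list(dag.variables),
                "score": dag.score,
                "edges": [
                    {"u": sorted(e)[0], "v": sorted(e)[1], "sign": s, "log_or": m_}
                    for e, (s, m_) in sorted(skel.edges.items(), key=lambda kv: sorted(kv[0]))
                ],
                "loops": [
                    {"cycle": list(l.cycle), "net_sign": l.net_sign} for l in loops
                ],
            }
            (out / "net.json").write_text(json.dumps(net, indent=2))
            manifest["outputs"]["network"] = "net.json"
            manifest["stages_run"].append("network")

        stage = "cluster"
        if config.stages.get("cluster", True):
            _log("cluster: two-way agglomerative clustering")
            m = cohort.core_marker_matrix()
            tum = cluster(m, metric=config.metric, linkage=config.linkage)
            feat = cluster(m.T, metric=config.metric, linkage=config.linkage)
            tree = {
                "tumours": {"items": list(tum.items),
                            "merges": tum.linkage.tolist()},
                "features": {"items": list(feat.items),
                             "merges": feat.linkage.tolist(),
                             "leaf_order": list(feat.leaf_order())},
            }
            (out / "tree.json").write_text(json.dumps(tree, indent=2))
            manifest["outputs"]["cluster"] = "tree.json"
            manifest["stages_run"].append("cluster")

        stage = "survive"
        if config.stages.get("survive", True):
            _log("survive: Cox one-vs-rest + KM by group")
            fits = group_survival_analysis(cohort, mode="one_vs_rest",
                                           include_msi=False)
            surv: dict = {}
            for name, fit in fits.items():
                if isinstance(fit, str):
                    surv[name] = {"error": fit}
                else:
                    surv[name] = {
                        "hr": fit.hr(name), "ci": list(fit.ci(name)),
                        "p": float(fit.terms.loc[name, "p"]),
                        "n": fit.n, "events": fit.events,
                    }
            df = cohort.df
            ok = df["group"].notna() & (df["group"] != "unclassifiable")
            curves = km_estimate(df.loc[ok, "dfs_years"], df.loc[ok, "dfs_event"],
                                 df.loc[ok, "group"])
            surv["km_5yr"] = {g: c.at(5.0) for g, c in sorted(curves.items())}
            (out / "survival.json").write_text(json.dumps(surv, indent=2, sort_keys=True))
            manifest["outputs"]["survival"] = "survival.json"
            manifest["stages_run"].append("survive")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    skipped = [s for s in _STAGES if s not in manifest["stages_run"]]
    report = _render_report(out, manifest, skipped)
    (out / "report.html").write_text(report)
    manifest["outputs"]["report"] = "report.html"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log(f"done: {out}/manifest.json")
    return manifest


def _render_report(out: Path, manifest: dict, skipped: list[str]) -> str:
    """Minimal static HTML report stitched from the stage outputs."""
    parts = [
        "<html><head><title>crcmolclass report</title></head><body>",
        "<h1>Molecular classification pipeline report</h1>",
        f"<p>seed {manifest['seed']}, config {manifest['config_hash']}, "
        f"version {manifest['version']}</p>",
    ]
    if skipped:
        parts.append(f"<p>Skipped stages: {', '.join(skipped)}</p>")
    summary = out / "summary.json"
    if summary.exists():
        counts = json.loads(summary.read_text())
        parts.append("<h2>Molecular groups</h2><table border=1><tr><th>group</th>"
                     "<th>n</th></tr>")
        for g, n in sorted(counts["counts"].items()):
            parts.append(f"<tr><td>{g}</td><td>{n}</td></tr>")
        parts.append("</table>")
        parts.append(f"<p>Groups 1-5 cover "
                     f"{100 * counts['coverage_groups_1_to_5']:.1f}% of tumours.</p>")
    net = out / "net.json"
    if net.exists():
        data = json.loads(net.read_text())
        parts.append("<h2>Primary associations (signed skeleton)</h2><ul>")
        for e in data["edges"]:
            parts.append(f"<li>{e['u']} – {e['v']}: {e['sign']} "
                         f"(conditional log-OR {e['log_or']:.2f})</li>")
        parts.append("</ul>")
        if data["loops"]:
            parts.append("<h3>Association loops</h3><ul>")
            for l in data["loops"]:
                parts.append(f"<li>{' – '.join(l['cycle'])} (net {l['net_sign']})</li>")
            parts.append("</ul>")
    surv = out / "survival.json"
    if surv.exists():
        data = json.loads(surv.read_text())
        parts.append("<h2>Disease-free survival (one-vs-rest Cox)</h2>"
                     "<table border=1><tr><th>group</th><th>HR</th><th>95% CI</th>"
                     "<th>p</th></tr>")
        for g in sorted(k for k in data if k.startswith("group")):
            v = data[g]
            if "error" in v:
                parts.append(f"<tr><td>{g}</td><td colspan=3>{v['error']}</td></tr>")
            else:
                parts.append(
                    f"<tr><td>{g}</td><td>{v['hr']:.2f}</td>"
                    f"<td>{v['ci'][0]:.2f}–{v['ci'][1]:.2f}</td>"
                    f"<td>{v['p']:.3g}</td></tr>")
        parts.append("</table>")
        if "km_5yr" in data:
            parts.append("<p>5-year KM survival by group: " + ", ".join(
                f"{g}: {s:.2f}" for g, s in data["km_5yr"].items()) + "</p>")
    parts.append("</body></html>")
    return "\n".join(parts)
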