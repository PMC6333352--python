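"""End-to-end orchestration of the two-cohort differential co-expression study.

Stage order: preprocess -> wgcna (per dataset) -> neri (per dataset) ->
combine -> replication -> mset -> hubs -> robustness (optional).  Every
output file lands under the configured ``out_dir`` and is recorded in a
manifest with a content hash; a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import evaluate as ev
from . import io as cio
from . import neri as nr
from . import preprocess as pp
from .config import ConfigError, RunConfig

log = logging.getLogger("coexprio")

STAGES = [
    "preprocess",
    "wgcna",
    "neri",
    "combine",
    "replication",
    "mset",
    "hubs",
    "robustness",
]

_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FMT, index=index)


def _derive_seed(base: int, stage: str, extra: str = "") -> int:
    digest = hashlib.sha256(f"{base}:{stage}:{extra}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stages": [],
        "outputs": {},
        "inputs": {},
        "params": {
            "rng_seed": config.rng_seed,
            "wgcna": config.wgcna,
            "neri": config.neri,
            "mset": config.mset,
            "robustness": config.robustness,
        },
    }
    for ds in config.datasets:
        manifest["inputs"][ds.expression] = _sha256(Path(ds.expression))
        manifest["inputs"][ds.metadata] = _sha256(Path(ds.metadata))
    for path in (config.ppi, config.seeds, config.references):
        manifest["inputs"][path] = _sha256(Path(path))

    def emit(df, name, index=True):
        path = out / name
        _write(df, path, index=index)
        manifest["outputs"][name] = _sha256(path)

    def stage_done(name, note=""):
        manifest["stages"].append({"name": name, "status": note or "ok"})
        log.info("stage %s: %s", name, note or "ok")

    # ---------------- preprocess ----------------
    data = {}
    for ds in config.datasets:
        if ds.probes:
            values = pd.read_csv(ds.probes, sep="\t", index_col=0)
            probe_map = pd.read_csv(ds.probe_map, sep="\t", index_col=0).iloc[:, 0]
            detected = pd.read_csv(ds.detection, sep="\t", index_col=0).astype(bool)
            meta = cio.read_metadata(ds.metadata)
            expr = pp.filter_and_summarize(
                pp.ProbeMatrix(values, probe_map, detected), meta["condition"]
            )
        else:
            expr = cio.read_expression(ds.expression)
            meta = cio.read_metadata(ds.metadata)
        excl = set(config.wgcna.get("exclude_samples", []))
        keep = [c for c in expr.columns if c not in excl]
        expr, meta = expr[keep], meta.loc[keep]
        n_comp = min(5, min(expr.shape) - 1)
        svd = pp.svd_screen(expr, meta.drop(columns=["condition"]), n_components=n_comp)
        demo = pp.demographic_tests(meta)
        emit(svd, f"{ds.name}_svd_screen.tsv", index=False)
        emit(demo, f"{ds.name}_demographics.tsv", index=False)
        cond = meta["condition"]
        ctl_label, case_label = sorted(cond.unique())[0], sorted(cond.unique())[-1]
        # convention: controls are labelled CTL; anything else is the case group
        if "CTL" in set(cond.unique()):
            ctl_label = "CTL"
            case_label = sorted(set(cond.unique()) - {"CTL"})[0]
        data[ds.name] = {
            "expr": expr,
            "meta": meta,
            "control": expr.loc[:, cond == ctl_label],
            "case": expr.loc[:, cond == case_label],
            "demographics": demo,
        }
    stage_done("preprocess")

    # ---------------- wgcna ----------------
    for name, d in data.items():
        wp = config.wgcna
        scan_ctl = cx.select_soft_threshold(
            d["control"], wp["beta_candidates"], wp["r2_min"]
        )
        scan_case = cx.select_soft_threshold(d["case"], wp["beta_candidates"], wp["r2_min"])
        betas = [b for b in (scan_ctl.chosen_beta, scan_case.chosen_beta) if b is not None]
        if betas:
            beta = max(betas)
        else:
            # no candidate reached the fit threshold: use the conventional
            # unsigned-network default power
            beta = int(config.wgcna.get("fallback_beta", 6))
            log.warning("%s: no beta reached R2 threshold; using default beta=%d", name, beta)
        adj = cx.adjacency_matrix(d["control"], beta)
        tom = cx.compute_tom(adj)
        modules = cx.detect_modules(
            d["control"],
            tom,
            min_module_size=wp["min_module_size"],
            merge_cut_height=wp["merge_cut_height"],
            deepsplit=wp["deepsplit"],
            adjacency=adj,
        )
        preservation = cx.module_preservation(
            d["control"],
            d["case"],
            modules.labels,
            beta=beta,
            n_permutations=wp["n_permutations"],
            rng_seed=_derive_seed(config.rng_seed, "preservation", name),
        )
        # eigengenes over ALL samples for the trait screen
        me_all, _, _ = cx.eigengene_kme(d["expr"], modules.labels)
        traits = cx.trait_association(me_all, d["meta"])
        least = preservation["median_rank"].idxmax()
        d.update(
            beta=beta,
            modules=modules,
            preservation=preservation,
            least_preserved=least,
            wgcna_list=modules.genes_of(least),
        )
        scan = scan_ctl.scan.merge(
            scan_case.scan, on="beta", suffixes=("_control", "_case")
        )
        emit(scan, f"{name}_soft_threshold.tsv", index=False)
        assign = pd.DataFrame(
            {
                "module": modules.labels,
                "ktotal": modules.ktotal,
            }
        )
        own_kme = [
            modules.kme.at[g, m] if m != cx.GREY and m in modules.kme.columns else np.nan
            for g, m in modules.labels.items()
        ]
        assign["kme"] = own_kme
        emit(assign, f"{name}_modules.tsv")
        emit(modules.me, f"{name}_eigengenes.tsv")
        emit(preservation, f"{name}_preservation.tsv")
        emit(traits, f"{name}_trait_association.tsv", index=False)
    stage_done("wgcna")

    # ---------------- neri ----------------
    graph = nr.merge_ppi([cio.read_edge_table(config.ppi)])
    seeds = cio.read_seeds(config.seeds)
    for name, d in data.items():
        np_cfg = config.neri
        table, top = nr.run_neri(
            graph,
            seeds,
            d["control"],
            d["case"],
            score=np_cfg["score"],
            fraction=np_cfg["fraction"],
            path_cap=np_cfg["path_cap"],
        )
        d.update(neri_table=table, neri_top=top, neri_background=sorted(table.index))
        emit(table, f"{name}_neri_importance.tsv")
        emit(top, f"{name}_neri_top.tsv")
    stage_done("neri")

    # ---------------- combine ----------------
    for name, d in data.items():
        combined = ev.combine(d["wgcna_list"], list(d["neri_top"].index))
        d["combined"] = combined
        emit(combined, f"{name}_combined.tsv", index=False)
        # plain one-column exports for external enrichment services
        for tag, genes in (
            ("wgcna", d["wgcna_list"]),
            ("neri", list(d["neri_top"].index)),
            ("combined", list(combined["gene"])),
        ):
            emit(pd.DataFrame({"gene": sorted(genes)}), f"{name}_{tag}_genes.txt", index=False)
    stage_done("combine")

    # ---------------- replication ----------------
    names = [ds.name for ds in config.datasets]
    if len(names) >= 2:
        a, b = names[0], names[1]
        rows = []
        bg_expr = sorted(set(data[a]["expr"].index) & set(data[b]["expr"].index))
        bg_neri = sorted(set(data[a]["neri_background"]) & set(data[b]["neri_background"]))
        for method, bg in (("wgcna", bg_expr), ("neri", bg_neri), ("combined", sorted(set(bg_expr) | set(bg_neri)))):
            la = (
                data[a]["wgcna_list"]
                if method == "wgcna"
                else list(data[a]["neri_top"].index)
                if method == "neri"
                else list(data[a]["combined"]["gene"])
            )
            lb = (
                data[b]["wgcna_list"]
                if method == "wgcna"
                else list(data[b]["neri_top"].index)
                if method == "neri"
                else list(data[b]["combined"]["gene"])
            )
            overlap, p = ev.replication_overlap(la, lb, bg)
            rows.append(
                {
                    "method": method,
                    "list_1": len(set(la) & set(bg)),
                    "list_2": len(set(lb) & set(bg)),
                    "background": len(bg),
                    "overlap": len(overlap),
                    "p_value": p,
                }
            )
        emit(pd.DataFrame(rows), "replication.tsv", index=False)
        stage_done("replication")
    else:
        stage_done("replication", "skipped (single dataset)")

    # ---------------- mset ----------------
    references = cio.read_gmt(config.references)
    rows = []
    for name, d in data.items():
        bg_wgcna = sorted(d["expr"].index)
        bg_neri = d["neri_background"]
        bg_combined = sorted(set(bg_wgcna) | set(bg_neri))
        queries = {
            "wgcna": (d["wgcna_list"], bg_wgcna),
            "neri": (list(d["neri_top"].index), bg_neri),
            "combined": (list(d["combined"]["gene"]), bg_combined),
        }
        for method, (query, bg) in queries.items():
            for ref_name, ref in references.items():
                res = ev.mset(
                    query,
                    bg,
                    ref,
                    n_permutations=config.mset["n_permutations"],
                    rng_seed=_derive_seed(config.rng_seed, "mset", f"{name}:{method}:{ref_name}"),
                )
                rows.append(
                    {
                        "dataset": name,
                        "method": method,
                        "reference": ref_name,
                        "query_size": res.query_size,
                        "background_size": res.background_size,
                        "reference_in_background": res.reference_size,
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "p_value": res.p_value,
                    }
                )
    mset_report = pd.DataFrame(rows)
    emit(mset_report, "mset.tsv", index=False)
    stage_done("mset")

    # ---------------- hubs ----------------
    rows = []
    for name, d in data.items():
        wh = ev.hubs_wgcna(d["modules"], d["least_preserved"])
        nh = ev.hubs_neri(list(d["neri_top"].index), graph)
        for method, report in (("wgcna", wh), ("neri", nh)):
            for kind, genes in (("kme", report.kme_hubs), ("window", report.window_hubs)):
                for g in genes:
                    rows.append({"dataset": name, "method": method, "rule": kind, "gene": g})
        d.update(wgcna_hubs=wh, neri_hubs=nh)
    emit(pd.DataFrame(rows, columns=["dataset", "method", "rule", "gene"]), "hubs.tsv", index=False)
    stage_done("hubs")

    # ---------------- robustness ----------------
    if config.robustness.get("enabled"):
        for name, d in data.items():
            rb = nr.seed_robustness(
                graph,
                seeds,
                d["control"],
                d["case"],
                fractions=tuple(config.robustness["fractions"]),
                n_sets=config.robustness["n_sets"],
                tops=tuple(config.robustness["tops"]),
                rng_seed=_derive_seed(config.rng_seed, "robustness", name),
                score=config.neri["score"],
                path_cap=config.neri["path_cap"],
            )
            d["robustness"] = rb
            emit(rb, f"{name}_robustness.tsv", index=False)
        stage_done("robustness")
    else:
        stage_done("robustness", "skipped (disabled)")

    cio.write_json(manifest, out / "manifest.json")
    # keep result objects available to callers (tests, acceptance script)
    manifest["_data"] = data
    return manifest
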