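"""End-to-end pipeline: simulate -> preprocess -> integrate -> compartments
-> associate -> modules -> markers, driven by one config mapping.

Every stage writes its artifact under the run directory and contributes a
content hash to the machine-readable :class:`RunReport`, so a rerun with
the same config and seed produces a byte-identical report.  When planted
truth is available (simulated input), the report additionally carries
truth-comparison metrics: per-species boundary error, adjusted Rand index
of recovered vs planted module membership, recall of planted module
orthogroups in the conserved AP set, and the fraction of selected
discriminant markers that are planted signal genes.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import io as gio
from .synthetic import SyntheticConfig, generate
from .preprocess import run_preprocess
from .ortho import (OrthologyTable, filter_orthogroups, resolve,
                    expand_tf_flags, integrate)
from .compartments import segment_correlation, detect_boundary
from .apassoc import screen_conserved
from .modules_ap import extract_modules, module_position
from .discriminant import fit_splsda, cv_select_keepX, rank_markers

DEFAULTS = {
    "preprocess": {"min_count": 10, "min_samples": None,
                   "method": "log2cpm", "top_k": 2000},
    "ortho": {"hard_max": 120, "soft_max": 80, "balance_ratio": 3.0},
    "compartments": {"beta_min": 0.02, "ci": 0.95},
    "assoc": {"q": 0.05, "degree": 3, "tf_only": False},
    "modules": {"k": "auto"},
    "markers": {"ncomp": 2, "keepx_grid": [5, 10, 25, 50],
                "tolerance": 0.02, "groups": "compartment"},
}


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    hashes: dict = field(default_factory=dict)
    compartments: dict = field(default_factory=dict)
    conserved_size: int = 0
    terminal_size: int = 0
    modules: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    truth_metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "hashes": self.hashes,
            "compartments": self.compartments,
            "conserved_size": self.conserved_size,
            "terminal_size": self.terminal_size,
            "modules": self.modules,
            "markers": self.markers,
            "truth_metrics": self.truth_metrics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


class ConfigError(ValueError):
    pass


def _merge(section: str, cfg: dict) -> dict:
    out = dict(DEFAULTS[section])
    out.update(cfg.get(section, {}) or {})
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str, t0: float) -> None:
    print(f"[gutmap +{time.perf_counter() - t0:7.2f}s] {msg}",
          file=sys.stderr)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    for key in ("seed", "outdir"):
        if key not in cfg:
            raise ConfigError(f"config missing required key {key!r}")
    unknown = set(cfg) - {"seed", "outdir", "simulate", *DEFAULTS}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict | str | Path) -> RunReport:
    """Execute the full pipeline from a config mapping or YAML path."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report = RunReport(config=json.loads(json.dumps(config, sort_keys=True)))

    # ---- simulate ----------------------------------------------------------
    sim_kwargs = dict(config.get("simulate", {}) or {})
    sim_kwargs["seed"] = seed
    scfg = SyntheticConfig(**sim_kwargs)
    datasets, seqs, orthology, truth = generate(scfg)
    _log(f"simulated {scfg.n_species} species, "
         f"{scfg.n_orthogroups} orthogroups", t0)
    written = []
    for ds in datasets:
        written += [outdir / f"{ds.species}_counts.tsv",
                    outdir / f"{ds.species}_meta.tsv"]
        gio.write_counts_tsv(ds, written[-2])
        gio.write_meta_tsv(ds, written[-1])
    table = OrthologyTable(orthology)
    table.write_tsv(outdir / "Orthogroups.tsv")
    for sp, by_gene in seqs.items():
        gio.write_fasta(by_gene, outdir / f"{sp}_proteins.fasta")
        written.append(outdir / f"{sp}_proteins.fasta")
    truth.to_json(outdir / "truth.json")
    written += [outdir / "Orthogroups.tsv", outdir / "truth.json"]
    for f in sorted(written):
        report.hashes[f.name] = _sha256(f)

    # ---- preprocess --------------------------------------------------------
    pp = _merge("preprocess", config)
    seg_level, zscored = {}, {}
    for ds in datasets:
        seg, z = run_preprocess(ds, min_count=pp["min_count"],
                                min_samples=pp["min_samples"],
                                method=pp["method"])
        seg_level[ds.species] = seg
        zscored[ds.species] = z
        gio.write_counts_tsv(z, outdir / f"{ds.species}_zscored.tsv")
        report.hashes[f"{ds.species}_zscored.tsv"] = _sha256(
            outdir / f"{ds.species}_zscored.tsv")
    _log("preprocessed all species", t0)

    # ---- orthology + integration ------------------------------------------
    oc = _merge("ortho", config)
    table_f = filter_orthogroups(table, hard_max=oc["hard_max"],
                                 soft_max=oc["soft_max"],
                                 balance_ratio=oc["balance_ratio"])
    resolved = resolve(table_f, seqs)
    resolved.write_tsv(outdir / "resolved_map.tsv")
    gene_flags = {
        g: True
        for og, flagged in truth.tf_flag.items() if flagged
        for sp in table_f.groups.get(og, {})
        for g in table_f.groups[og][sp]
    }
    og_tf = expand_tf_flags(set(gene_flags), table_f)
    im = integrate(zscored, resolved, tf_flags=og_tf)
    im.write_tsv(outdir / "integrated.tsv")
    report.hashes["integrated.tsv"] = _sha256(outdir / "integrated.tsv")
    _log(f"integrated matrix: {im.values.shape[0]} orthogroups x "
         f"{im.values.shape[1]} segments", t0)

    # ---- compartments ------------------------------------------------------
    cc = _merge("compartments", config)
    calls = {}
    for sp, seg in seg_level.items():
        C = segment_correlation(seg.values, top_k=pp["top_k"])
        calls[sp] = detect_boundary(C, beta_min=cc["beta_min"], ci=cc["ci"])
        report.compartments[sp] = calls[sp].to_dict()
    _log("compartments called", t0)

    # ---- AP association ----------------------------------------------------
    ac = _merge("assoc", config)
    assoc = screen_conserved(im, q_threshold=ac["q"], degree=ac["degree"],
                             tf_only=ac["tf_only"])
    report.conserved_size = int(assoc.conserved.sum())
    report.terminal_size = int(assoc.cross_species_terminal.sum())
    _log(f"conserved AP-associated set: {report.conserved_size}", t0)

    # ---- modules -----------------------------------------------------------
    mc = _merge("modules", config)
    conserved_im = im.subset(assoc.conserved_set)
    if conserved_im.values.shape[0] >= 6:
        ms = extract_modules(conserved_im, k=mc["k"])
        placement = module_position(ms, calls)
        report.modules = {
            "k": ms.k,
            "members": {str(m): members
                        for m, members in enumerate(ms.modules)},
            "deviations": placement[placement["deviates"]][
                ["module", "species"]].to_dict("records"),
        }
        placement.to_csv(outdir / "module_placement.tsv", sep="\t",
                         index=False)
    else:
        ms = None
        report.modules = {"k": 0, "members": {}, "deviations": []}
    _log(f"modules: k={report.modules['k']}", t0)

    # ---- markers -----------------------------------------------------------
    kc = _merge("markers", config)
    if kc["groups"] == "compartment":
        groups = np.array([
            "anterior" if rank < calls[sp].boundary else "posterior"
            for sp, rank in zip(im.col_meta["species"],
                                im.col_meta["ap_rank"])
        ])
    else:
        gdf = pd.read_csv(kc["groups"], sep="\t", index_col="sample")
        groups = gdf.loc[im.col_meta.index, "group"].to_numpy()
    species_labels = im.col_meta["species"].to_numpy()
    grid = [k for k in kc["keepx_grid"] if k <= im.values.shape[0]]
    chosen, curve = cv_select_keepX(im.values, groups, grid,
                                    species=species_labels, ncomp=1,
                                    tolerance=kc["tolerance"], seed=seed)
    model = fit_splsda(im.values, groups, chosen, ncomp=kc["ncomp"])
    model.optimal_keepX = chosen
    model.cv_errors = curve
    markers = rank_markers(model)
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    report.markers = {
        "optimal_keepX": chosen,
        "cv_error_curve": {int(k): (None if np.isnan(v) else float(v))
                           for k, v in curve.items()},
        "selected": markers["feature"].tolist(),
        "optimal_set": markers.loc[markers["in_optimal_set"],
                                   "feature"].tolist(),
    }
    _log(f"markers: keepX={chosen}", t0)

    # ---- truth comparison --------------------------------------------------
    report.truth_metrics = truth_metrics(truth, calls, assoc, ms, markers)
    report.to_json(outdir / "report.json")
    _log("report written", t0)
    return report


def truth_metrics(truth, calls, assoc, ms, markers: pd.DataFrame) -> dict:
    """Compare pipeline output against planted ground truth."""
    out: dict = {}
    errs = [abs(calls[sp].boundary - truth.boundary[sp]) for sp in calls]
    out["boundary_abs_error"] = {sp: int(abs(calls[sp].boundary
                                             - truth.boundary[sp]))
                                 for sp in calls}
    out["boundary_mean_abs_error"] = float(np.mean(errs))

    planted_modules = {og: mid for mid, members in
                       truth.module_members.items() for og in members}
    conserved = set(assoc.conserved_set)
    module_ogs = set(planted_modules)
    tested = set(assoc.conserved.index)
    present = module_ogs & tested
    if present:
        out["conserved_recall"] = float(
            len(conserved & present) / len(present))
    nulls = {og for og, a in truth.archetype.items()
             if a == "null"} & tested
    if nulls:
        out["conserved_null_rate"] = float(
            len(conserved & nulls) / len(nulls))

    if ms is not None:
        overlap = [og for og in ms.membership.index if og in planted_modules]
        if overlap:
            out["module_ari"] = float(adjusted_rand_score(
                [planted_modules[og] for og in overlap],
                [ms.membership[og] for og in overlap]))
            out["module_k"] = int(ms.k)

    term_truth = {og for og, a in truth.archetype.items()
                  if a == "terminal"} & tested
    if term_truth:
        found = set(assoc.terminal_set)
        out["terminal_recall"] = float(
            len(found & term_truth) / len(term_truth))

    if len(markers):
        sel = markers["feature"]
        nonnull = [og for og in sel if truth.archetype.get(og) != "null"]
        out["marker_signal_fraction"] = float(len(nonnull) / len(sel))
    return out
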