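"""Config-driven orchestration of the full analysis chain.

Stages: expression IO -> differential expression -> gene-set scoring ->
stability selection -> signature fit -> external prediction -> survival ->
microenvironment. Every stage writes its artifact under a numbered
subdirectory of the output directory and is recorded in a run manifest
(inputs' checksums, parameters, seeds, row counts), which makes repeated
runs byte-identical and supports incremental re-execution: on ``resume``,
a stage whose recorded input fingerprint is unchanged and whose outputs
are intact is skipped.

Seeding: one master seed deterministically derives a per-stage seed as
``(master_seed + crc32(stage_name)) % 2**31`` so stages consume
independent, reproducible randomness streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, gsea, io, microenv, signature, stability, survival
from ._models import FAMILIES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds for one pipeline run."""

    matrix: str
    labels: str
    out_dir: str
    seed: int
    probe_map: str | None = None
    gmt: str | None = None
    external_matrix: str | None = None
    survival_table: str | None = None
    signature_matrix: str | None = None
    stemness_weights: str | None = None
    lfc_min: float = 1.0
    q_max: float = 0.05
    top_frac: float = 0.2
    min_occurrence: int = 8
    rounds: int = 10
    call_threshold: float = 0.5
    families: list[str] = field(default_factory=lambda: list(FAMILIES))
    final_family: str = "linear_svm"
    roc_horizons: list[float] = field(default_factory=lambda: [12.0, 36.0, 60.0])

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must be in (0, 1]")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be nonnegative")
        if not 0 < self.call_threshold < 1:
            raise ValueError("call_threshold must be in (0, 1)")
        if self.min_occurrence > self.rounds:
            raise ValueError(
                f"min_occurrence ({self.min_occurrence}) cannot exceed rounds "
                f"({self.rounds})"
            )
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown model families: {unknown}")
        if self.final_family not in self.families:
            raise ValueError("final_family must be among the configured families")
        missing = [
            p
            for p in (
                self.matrix,
                self.labels,
                self.probe_map,
                self.gmt,
                self.external_matrix,
                self.survival_table,
                self.signature_matrix,
                self.stemness_weights,
            )
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + zlib.crc32(stage.encode())) % 2**31


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Runner:
    def __init__(self, config: PipelineConfig, resume: bool):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"config": asdict(config), "stages": []}
        self.previous: dict[str, dict] = {}
        if resume:
            mpath = self.out / "run_manifest.json"
            if mpath.exists():
                prev = json.loads(mpath.read_text())
                self.previous = {s["name"]: s for s in prev.get("stages", [])}
        self.upstream_hash = hashlib.sha256()
        for p in (config.matrix, config.labels):
            self.upstream_hash.update(_sha256(Path(p)).encode())

    def stage(self, name: str, params: dict, compute) -> dict[str, Path]:
        """Run or skip one stage; ``compute(stage_dir)`` returns output paths."""
        stage_dir = self.out / name
        fingerprint = hashlib.sha256(
            (self.upstream_hash.hexdigest() + json.dumps(params, sort_keys=True)).encode()
        ).hexdigest()
        prev = self.previous.get(name)
        outputs: dict[str, Path] | None = None
        if prev and prev["fingerprint"] == fingerprint:
            paths = {k: Path(v) for k, v in prev["outputs"].items()}
            if all(p.exists() and _sha256(p) == prev["checksums"][k] for k, p in paths.items()):
                outputs = paths
                executed = False
        if outputs is None:
            t0 = time.time()
            stage_dir.mkdir(parents=True, exist_ok=True)
            outputs = compute(stage_dir)
            executed = True
            logger.info("stage %s: %.2fs", name, time.time() - t0)
        checksums = {k: _sha256(p) for k, p in outputs.items()}
        record = {
            "name": name,
            "fingerprint": fingerprint,
            "executed": executed,
            "outputs": {k: str(p) for k, p in outputs.items()},
            "checksums": checksums,
        }
        self.manifest["stages"].append(record)
        for c in sorted(checksums.values()):
            self.upstream_hash.update(c.encode())
        return outputs


def run(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    config.validate()
    c = config
    r = _Runner(c, resume)

    # -- 01 io ------------------------------------------------------------
    def do_io(d: Path) -> dict[str, Path]:
        m = io.read_matrix(c.matrix)
        if c.probe_map:
            m = io.collapse_probes(m, io.read_probe_map(c.probe_map))
        z = io.zscore(m)
        raw_p, z_p = d / "expression_raw.tsv", d / "expression_zscore.tsv"
        io.write_matrix(m, raw_p)
        io.write_matrix(z, z_p)
        return {"raw": raw_p, "zscore": z_p}

    io_out = r.stage("01_io", {"probe_map": c.probe_map}, do_io)
    m_raw = io.read_matrix(io_out["raw"])
    m_z = io.read_matrix(io_out["zscore"])
    m_z.scale_tag = "zscore"
    labels = io.read_labels(c.labels)

    # -- 02 deg -----------------------------------------------------------
    def do_deg(d: Path) -> dict[str, Path]:
        records = diffexpr.moderated_t(m_raw, labels)
        result = diffexpr.filter_degs(records, lfc_min=c.lfc_min, q_max=c.q_max)
        p = d / "deg_table.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("# log2FC = mean(nonresponders) - mean(responders)\n")
            result.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        logger.info(
            "DEGs: %d total (%d up, %d down) of %d genes tested",
            result.n_total, result.n_up, result.n_down, len(records),
        )
        return {"deg_table": p}

    deg_out = r.stage("02_deg", {"lfc_min": c.lfc_min, "q_max": c.q_max}, do_deg)
    deg_table = pd.read_csv(deg_out["deg_table"], sep="\t", comment="#")
    deg_genes = list(deg_table["gene"])

    # -- 03 gsea (optional) -------------------------------------------------
    if c.gmt:
        def do_gsea(d: Path) -> dict[str, Path]:
            sets = io.read_gmt(c.gmt)
            scores = gsea.sample_enrichment(m_raw, sets)
            contrasts = gsea.contrast_sets(scores, labels)
            sp, cp = d / "set_scores.tsv", d / "set_contrasts.tsv"
            scores.to_csv(sp, sep="\t", float_format="%.10g")
            contrasts.to_csv(cp, sep="\t", index=False, float_format="%.10g")
            return {"scores": sp, "contrasts": cp}

        r.stage("03_gsea", {"gmt": c.gmt}, do_gsea)

    # -- 04 select ----------------------------------------------------------
    m_deg = m_z.subset_genes(deg_genes)
    allowed = None
    if c.external_matrix:
        allowed = set(io.read_matrix(c.external_matrix).gene_ids)

    def do_select(d: Path) -> dict[str, Path]:
        outputs: dict[str, Path] = {}
        for family in c.families:
            res = stability.run_iterations(
                m_deg, labels, family,
                rounds=c.rounds, base_seed=c.stage_seed(f"04_select:{family}"),
            )
            table = stability.accumulate_occurrence(res, top_frac=c.top_frac)
            disp = table.copy()
            disp["occurrence"] = [f"{k}/{c.rounds}" for k in table["occurrence"]]
            tp = d / f"occurrence_{family}.tsv"
            disp.to_csv(tp, sep="\t", index=False, float_format="%.10g")
            lp = d / f"iterations_{family}.json"
            lp.write_text(json.dumps([
                {
                    "index": it.index,
                    "seed": it.seed,
                    "train": it.train_ids,
                    "test": it.test_ids,
                    "metrics": it.metrics.as_dict(),
                }
                for it in res
            ], indent=2))
            outputs[f"occurrence_{family}"] = tp
            outputs[f"iterations_{family}"] = lp
        return outputs

    sel_out = r.stage(
        "04_select",
        {
            "families": c.families,
            "rounds": c.rounds,
            "top_frac": c.top_frac,
            "seed": c.seed,
        },
        do_select,
    )
    occ = pd.read_csv(sel_out[f"occurrence_{c.final_family}"], sep="\t")
    occ["occurrence"] = occ["occurrence"].str.split("/").str[0].astype(int)
    selected = stability.select_genes(
        occ, min_occurrence=c.min_occurrence, allowed=allowed
    )

    # -- 05 fit -------------------------------------------------------------
    def do_fit(d: Path) -> dict[str, Path]:
        table, winner = signature.compare_models(
            m_z, labels, selected,
            families=tuple(c.families),
            rounds=c.rounds,
            base_seed=c.stage_seed("05_fit"),
        )
        model = signature.fit_final(
            m_z, labels, selected,
            family=c.final_family, seed=c.stage_seed("05_fit"),
        )
        model.threshold = c.call_threshold
        tp, mp = d / "model_comparison.tsv", d / "model.json"
        table.to_csv(tp, sep="\t", index=False, float_format="%.10g")
        model.to_json(mp)
        (d / "winner.txt").write_text(winner + "\n")
        return {"comparison": tp, "model": mp, "winner": d / "winner.txt"}

    fit_out = r.stage(
        "05_fit",
        {"genes": selected, "final_family": c.final_family, "seed": c.seed},
        do_fit,
    )
    model = signature.SignatureModel.from_json(fit_out["model"])

    # -- 06 predict -----------------------------------------------------------
    if c.external_matrix:
        ext = io.read_matrix(c.external_matrix)
        ext = io.zscore(ext)  # external cohort z-scored separately
    else:
        ext = m_z

    def do_predict(d: Path) -> dict[str, Path]:
        preds = signature.predict_cohort(model, ext)
        p = d / "predictions.tsv"
        preds.to_csv(p, sep="\t", index=False, float_format="%.10g")
        return {"predictions": p}

    pred_out = r.stage(
        "06_predict", {"external": c.external_matrix, "thr": c.call_threshold}, do_predict
    )
    preds = pd.read_csv(pred_out["predictions"], sep="\t")

    # -- 07 survival (optional) ----------------------------------------------
    if c.survival_table:
        def do_surv(d: Path) -> dict[str, Path]:
            surv = pd.read_csv(c.survival_table, sep="\t")
            merged = surv.merge(
                preds.rename(columns={"call": "predicted_nonresponse"}),
                on="sample",
            )
            results: dict = {"n": len(merged)}
            groups = merged["predicted_nonresponse"]
            if groups.nunique() == 2:
                chi2, p = survival.logrank(
                    merged["time"], merged["event"], groups
                )
                results["logrank"] = {"chi2": chi2, "p": p}
                covs = ["predicted_nonresponse"] + [
                    col for col in surv.columns
                    if col not in ("sample", "time", "event")
                ]
                uni = {
                    cv: survival.cox_fit(merged, [cv]).iloc[0].to_dict()
                    for cv in covs
                }
                results["cox_univariate"] = uni
                if len(covs) > 1:
                    multi = survival.cox_fit(merged, covs)
                    results["cox_multivariate"] = multi.to_dict(orient="records")
            else:
                results["warning"] = "predicted calls form a single group"
            results["time_dependent_auc"] = survival.time_dependent_roc(
                merged["probability"], merged["time"], merged["event"],
                horizons=tuple(c.roc_horizons),
            )
            km_paths: dict[str, Path] = {}
            for g, grp in merged.groupby("predicted_nonresponse"):
                kp = d / f"km_group{g}.tsv"
                survival.km_estimate(grp["time"], grp["event"]).to_csv(
                    kp, sep="\t", index=False, float_format="%.10g"
                )
                km_paths[f"km_group{g}"] = kp
            rp = d / "survival_results.json"
            rp.write_text(json.dumps(results, indent=2, default=float))
            return {"results": rp, **km_paths}

        r.stage("07_survival", {"horizons": c.roc_horizons}, do_surv)

    # -- 08 microenv (optional) ------------------------------------------------
    if c.signature_matrix or c.stemness_weights:
        raw_for_me = io.read_matrix(c.external_matrix) if c.external_matrix else m_raw
        call = pd.Series(
            preds["call"].to_numpy(), index=preds["sample"], name="label"
        )

        def do_microenv(d: Path) -> dict[str, Path]:
            outputs: dict[str, Path] = {}
            if c.signature_matrix:
                sig = io.read_signature_matrix(c.signature_matrix)
                fracs = microenv.deconvolve(raw_for_me, sig)
                fp = d / "cell_fractions.tsv"
                fracs.to_csv(fp, sep="\t", float_format="%.10g")
                outputs["fractions"] = fp
                if call.nunique() == 2:
                    cmp_ = microenv.compare_fractions(fracs, call)
                    cp = d / "fraction_contrasts.tsv"
                    cmp_.to_csv(cp, sep="\t", index=False, float_format="%.10g")
                    outputs["fraction_contrasts"] = cp
            if c.stemness_weights:
                w = io.read_weights(c.stemness_weights)
                stem = microenv.stemness_index(raw_for_me, w)
                sp = d / "stemness.tsv"
                stem.to_csv(sp, sep="\t", float_format="%.10g")
                outputs["stemness"] = sp
            return outputs

        r.stage(
            "08_microenv",
            {"sig": c.signature_matrix, "weights": c.stemness_weights},
            do_microenv,
        )

    mpath = r.out / "run_manifest.json"
    mpath.write_text(json.dumps(r.manifest, indent=2, sort_keys=True))
    return r.manifest
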