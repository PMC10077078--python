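"""End-to-end pipeline: simulate -> curate -> split -> train -> embed ->
reduce -> attribute -> drift -> evaluate, from one seed.

Every output file carries the run's configuration hash and seed (CSV files
as a leading ``#`` comment line, JSON files as fields), so any report can be
traced to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribute, cohort, drift, evaluate, io, model, reduce, synth
from .containers import CLASSES, EmbeddingSet
from .errors import NgtLifeError

log = logging.getLogger("ngtlife")


class StageError(NgtLifeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One source of truth for a pipeline run; sub-seeds derive from `seed`."""

    out_dir: str = "results/run"
    seed: int = 0
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    classifier: model.ClassifierConfig = field(default_factory=model.ClassifierConfig)
    ensemble_sides: tuple = (48, 64)
    reducer: reduce.ReducerConfig = field(
        default_factory=lambda: reduce.ReducerConfig(backend="linear")
    )
    drift: drift.DriftConfig = field(default_factory=drift.DriftConfig)
    drift_scenario: synth.DriftSpec | None = None
    n_boot: int = 2000
    make_figures: bool = False

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = synth.SynthConfig(**d["synth"])
        if "classifier" in d:
            c = dict(d["classifier"])
            for k in ("conv_widths", "augment"):
                if k in c:
                    c[k] = tuple(c[k])
            d["classifier"] = model.ClassifierConfig(**c)
        if "reducer" in d:
            d["reducer"] = reduce.ReducerConfig(**d["reducer"])
        if "drift" in d:
            d["drift"] = drift.DriftConfig(**d["drift"])
        if d.get("drift_scenario"):
            s = d["drift_scenario"]
            mag = s.get("magnitude", 0.0)
            d["drift_scenario"] = synth.DriftSpec(s["kind"],
                                                  tuple(mag) if isinstance(mag, list) else mag)
        if "ensemble_sides" in d:
            d["ensemble_sides"] = tuple(d["ensemble_sides"])
        return cls(**d)


def _write_csv(df: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full lifecycle; returns the report dict (also written to
    ``out_dir/report.json``).  Deterministic per seed: rerunning with the
    same config yields byte-identical CSV reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = f"ngtlife config={config.config_hash()} seed={config.seed}"
    report = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            log.info("stage %s ...", name)
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, e) from e
        return deco

    # -- simulate -----------------------------------------------------------
    scfg = synth.SynthConfig(**{**asdict(config.synth), "seed": config.seed})
    scfg.class_priors = tuple(scfg.class_priors)
    scfg.manufacturer_levels = tuple(tuple(m) for m in scfg.manufacturer_levels)
    scfg.department_levels = tuple(scfg.department_levels)
    scfg.age_distribution = tuple(scfg.age_distribution)
    manifest = stage("simulate")(lambda: synth.generate_manifest(scfg))
    _write_csv(manifest, out / "manifest.csv", note)
    report["stages"]["simulate"] = {"n_images": len(manifest)}

    # -- curate -------------------------------------------------------------
    def _curate():
        kept, excl = cohort.qc_filter(manifest)
        kept = cohort.keyword_filter(kept)
        cons = cohort.consensus_labels(kept)
        kept = kept.assign(consensus=cons).dropna(subset=["consensus"]).reset_index(drop=True)
        return kept, excl
    kept, exclusions = stage("qc")(_curate)
    io.write_exclusion_log(exclusions, out / "exclusions.jsonl")
    report["stages"]["qc"] = {"kept": len(kept), "excluded": len(exclusions)}

    # -- split --------------------------------------------------------------
    split = stage("split")(
        lambda: cohort.grouped_stratified_split(kept, seed=config.seed)
    )
    io.write_split(split.assignment, out / "split.csv", header_note=note)
    report["stages"]["split"] = {"fractions": split.fractions, "flagged": split.flagged}

    # -- render + train -----------------------------------------------------
    def _train():
        pixels, tips = synth.render_cohort(kept, scfg)
        which = np.array([split.assignment[r] for r in kept["record_id"]])
        tr, va, te = (which == "train", which == "validation", which == "test")
        y = kept["consensus"].to_numpy()
        base = model.ClassifierConfig(**{**asdict(config.classifier), "seed": config.seed})
        base.conv_widths = tuple(base.conv_widths)
        base.augment = tuple(base.augment)
        models = model.train_ensemble(
            pixels[tr], y[tr], pixels[va], y[va], sides=config.ensemble_sides,
            base_config=base, classes=CLASSES,
        )
        return pixels, tips, which, y, models
    pixels, tips, which, y, models = stage("train")(_train)
    for m in models:
        _write_csv(m.history, out / f"history_{m.config.input_side}px.csv", note)
        m.save(out / f"model_{m.config.input_side}px.npz")
    report["stages"]["train"] = {
        f"{m.config.input_side}px": {
            "epochs": int(len(m.history)),
            "best_val_loss": float(m.history.attrs["best_val_loss"]),
        }
        for m in models
    }

    # -- predict + evaluate -------------------------------------------------
    def _evaluate():
        te = which == "test"
        proba = model.ensemble_proba(models, pixels[te])
        cm = evaluate.confusion(y[te], proba, CLASSES)
        aucs = {
            cls: evaluate.roc_auc(proba[:, i], (y[te] == cls).astype(int),
                                  n_boot=config.n_boot, seed=config.seed)
            for i, cls in enumerate(CLASSES)
            if 0 < (y[te] == cls).sum() < len(proba)
        }
        table = evaluate.metrics_table(cm)
        ens_brier = evaluate.brier_score(proba, y[te], CLASSES)
        const_brier = [
            evaluate.brier_score(m.predict_proba(pixels[te]), y[te], CLASSES)
            for m in models
        ]
        cal = evaluate.calibration_curve(proba.max(axis=1),
                                         (proba.argmax(axis=1) ==
                                          np.array([CLASSES.index(t) for t in y[te]])).astype(int))
        return proba, cm, aucs, table, ens_brier, const_brier, cal
    proba, cm, aucs, table, ens_brier, const_brier, cal = stage("evaluate")(_evaluate)
    preds = pd.DataFrame(proba, columns=[f"p_{c}" for c in CLASSES])
    preds.insert(0, "record_id", kept.loc[which == "test", "record_id"].to_numpy())
    _write_csv(preds, out / "predictions.csv", note)
    _write_csv(table, out / "metrics.csv", note)
    report["stages"]["evaluate"] = {
        "confusion": cm.counts.tolist(),
        "auc": {c: {"auc": a.auc, "ci": [a.ci_low, a.ci_high]} for c, a in aucs.items()},
        "brier_ensemble": ens_brier,
        "brier_constituents": const_brier,
        "ece": cal.ece,
    }

    # -- embed + reduce -----------------------------------------------------
    def _embed():
        X = model.extract_embeddings(models, pixels)
        es = EmbeddingSet(X=X, record_id=kept["record_id"].to_numpy(),
                          labels=y, tags=kept[["manufacturer", "department",
                                               "sex", "view"]].reset_index(drop=True))
        red = reduce.fit_reducer(X[which == "train"],
                                 reduce.ReducerConfig(**{**asdict(config.reducer),
                                                         "seed": config.seed}))
        coords = red.transform(X)
        return es, red, coords
    es, red, coords = stage("embed")(_embed)
    coord_set = EmbeddingSet(X=coords, record_id=es.record_id, labels=es.labels,
                             tags=es.tags, provenance=["pipeline reduce"])
    io.write_embeddings(coord_set, out / "coords.csv", header_note=note)
    red.save(out / "reducer.npz")

    # -- attribute ----------------------------------------------------------
    def _attribute():
        tags = attribute.manifest_tags(kept.rename(columns={"consensus": "label"})
                                       .drop(columns=["label"], errors="ignore")
                                       .rename(columns={}), include_label=False)
        tags.insert(0, attribute.encode_tag("label", y))
        ranked = attribute.rank_tags(coords, tags)
        conf_tags = [t for t in tags if t.name in ("manufacturer", "age_days", "department")]
        cum = attribute.cumulative_r2(coords, conf_tags)
        return ranked, cum
    ranked, cum = stage("attribute")(_attribute)
    attr_df = pd.DataFrame([{"tag": r.tag, "r2": r.r2, "n": r.n, "rank": r.rank}
                            for r in ranked])
    _write_csv(attr_df, out / "attribution.csv", note)
    report["stages"]["attribute"] = {
        "r2": {r.tag: r.r2 for r in ranked},
        "cumulative_confounders": {"tags": cum.tag, "r2": cum.r2},
    }

    # -- drift --------------------------------------------------------------
    def _drift():
        ref = coords[which == "test"]
        dcfg = drift.DriftConfig(**{**asdict(config.drift), "seed": config.seed})
        if config.drift_scenario is None:
            pool = ref
        elif config.drift_scenario.kind == "mean_shift":
            shifted = synth.apply_drift(
                EmbeddingSet(X=ref, record_id=es.record_id[which == "test"]),
                config.drift_scenario,
            )
            pool = shifted.X
        else:
            drifted = synth.apply_drift(kept.loc[which == "test"].reset_index(drop=True),
                                        config.drift_scenario)
            px, _ = synth.render_cohort(drifted, scfg)
            pool = red.transform(model.extract_embeddings(models, px))
        return drift.monitor(ref, pool, dcfg)
    mon = stage("drift")(_drift)
    report["stages"]["drift"] = {
        "scenario": None if config.drift_scenario is None else asdict(config.drift_scenario),
        "p_median": mon.p_median, "p_q1": mon.p_q1, "p_q3": mon.p_q3,
        "drift": mon.drift, "alpha": mon.alpha,
        "per_batch": [{"D": b.D, "p": b.p} for b in mon.batches],
    }

    # -- reader study analog -------------------------------------------------
    def _readers():
        ratings = synth.synth_reader_ratings(seed=config.seed)
        res = {}
        for phase in ("unaided", "aided"):
            sub = ratings[ratings["phase"] == phase]
            wide = sub.pivot(index="record_id", columns="reader", values="decision")
            mat, mean, sd = evaluate.kappa_matrix(wide)
            truth = sub.drop_duplicates("record_id").set_index("record_id")["consensus"]
            per_reader = [
                evaluate.cohen_kappa(wide[r], truth.loc[wide.index]).kappa
                for r in wide.columns
            ]
            res[phase] = {"interreader_mean": mean, "interreader_sd": sd,
                          "vs_consensus": per_reader}
        t, p, dof = evaluate.paired_kappa_test(res["unaided"]["vs_consensus"],
                                               res["aided"]["vs_consensus"])
        res["paired_t"] = {"t": t, "p": p, "df": dof}
        return res
    report["stages"]["reader_study"] = stage("reader-study")(_readers)

    if config.make_figures:
        from . import figures
        stage("figures")(lambda: figures.render_all(report, cal, aucs, out))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
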