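"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the study workflow: load or generate the corpus, apply
the >=10-message inclusion filter, preprocess, induce (or load) the
dictionary, evaluate it against gold tags where available, classify the
whole corpus, run the monthly-prevalence AR(1)+dummy tests, and fit the
issue logistic regressions and pairwise phi associations.  Every artifact
is a plain CSV/JSON/text file listed in a run manifest; identical
config+seed reproduces byte-identical CSVs.

A single global seed is fanned out deterministically to the corpus
generator and classifier training, so one integer reproduces the run.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import association as assoc
from .classify import assignments_to_csv, classify_docs
from .corpus import (
    ISSUES,
    STRATEGIES,
    THEMES,
    Corpus,
    corpus_summary,
    filter_min_messages,
    read_corpus,
    write_corpus,
)
from .lexicon import (
    InductionConfig,
    Lexicon,
    evaluate_lexicon,
    induce_lexicon,
    prune_uninformative,
    rank_features,
)
from .preprocess import PreprocessConfig, fit_tfidf, tokenize_corpus
from .synthetic import GeneratorConfig, generate_corpus, truth_to_frame
from .trends import Ar1DummyModel, TrendDesignError, prevalence_series, trend_report

logger = logging.getLogger("chatthemes")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def derive_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (kept below 2**31)."""
    return int(np.random.SeedSequence([int(global_seed), stage]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    # exactly one input source
    corpus_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    # exactly one lexicon source
    lexicon_path: Optional[str] = None  # None -> induce
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    induction: InductionConfig = field(default_factory=InductionConfig)
    min_messages: int = 10
    tfidf_min_df: int = 1
    auto_refine: bool = True  # greedy agreement-based pruning of induced terms
    induce_on_n: int = 1000  # size of the tagged subset used for induction
    break_month: tuple = (2020, 3)
    lb_lags: Optional[int] = None
    issues: tuple = ISSUES
    pandemic_dummy: bool = False
    out_dir: str = "chatthemes_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.corpus_path is None) == (self.generator is None):
            raise ValueError("exactly one of corpus_path / generator must be set")

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        if "generator" in obj and obj["generator"] is not None:
            gen = dict(obj["generator"])
            for key in ("start", "end", "break_month"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            obj["generator"] = GeneratorConfig(**gen)
        if "preprocess" in obj and obj["preprocess"] is not None:
            pp = dict(obj["preprocess"])
            if "stopwords" in pp:
                pp["stopwords"] = frozenset(pp["stopwords"])
            if "ngram_orders" in pp:
                pp["ngram_orders"] = frozenset(pp["ngram_orders"])
            obj["preprocess"] = PreprocessConfig(**pp)
        if "induction" in obj and obj["induction"] is not None:
            obj["induction"] = InductionConfig(**obj["induction"])
        if "break_month" in obj:
            obj["break_month"] = tuple(obj["break_month"])
        if "issues" in obj:
            obj["issues"] = tuple(obj["issues"])
        return cls(**obj)


def _tagged_theme_subset(corpus: Corpus, max_n: int) -> Corpus:
    """Conversations whose six theme flags are all known, up to max_n."""
    keep = []
    for conv in corpus.conversations:
        ls = corpus.labels.get(conv.id)
        if ls is not None and all(ls.themes[t] is not None for t in THEMES):
            keep.append(conv)
        if len(keep) >= max_n:
            break
    ids = {c.id for c in keep}
    return Corpus(conversations=keep, labels={i: corpus.labels[i] for i in ids})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    The manifest lists every artifact written, the config echo, the seed,
    stage timings and warnings.  On stage failure the manifest is written
    with a FAILED marker before the error propagates.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "artifacts": [],
        "timings_s": {},
        "warnings": [],
        "config": _config_echo(config),
        "status": "RUNNING",
    }

    def emit(name: str):
        manifest["artifacts"].append(name)
        return out / name

    def finish_stage(stage: str, t0: float):
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    stage = "load"
    try:
        # ---- load or generate ------------------------------------------
        t0 = time.perf_counter()
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=derive_seed(config.seed, 0))
            corpus, truth = generate_corpus(gen)
            write_corpus(corpus, emit("corpus.jsonl"), format="jsonl")
            truth_to_frame(truth).to_csv(emit("ground_truth.csv"), index=False)
        else:
            corpus = read_corpus(config.corpus_path, format="jsonl")
            truth = None
        finish_stage(stage, t0)

        # ---- inclusion filter ------------------------------------------
        stage = "filter"
        t0 = time.perf_counter()
        n_before = len(corpus)
        corpus = filter_min_messages(corpus, config.min_messages)
        logger.info("filter: kept %d of %d conversations", len(corpus), n_before)
        summ = corpus_summary(corpus)
        with open(emit("corpus_summary.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(summ), fh, indent=1, sort_keys=True, default=str)
        finish_stage(stage, t0)

        # ---- preprocess -------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        docs = tokenize_corpus(corpus, config.preprocess)
        finish_stage(stage, t0)

        # ---- lexicon: induce or load -----------------------------------
        stage = "lexicon"
        t0 = time.perf_counter()
        if config.lexicon_path is not None:
            lexicon = Lexicon.from_json(config.lexicon_path)
        else:
            tagged = _tagged_theme_subset(corpus, config.induce_on_n)
            if not tagged.conversations:
                raise PipelineError("lexicon induction requires gold theme labels")
            tagged_docs = tokenize_corpus(tagged, config.preprocess)
            tfidf = fit_tfidf(
                tagged_docs, min_df=config.tfidf_min_df,
                ngram_orders=config.preprocess.ngram_orders,
            )
            ind = dataclasses.replace(config.induction, seed=derive_seed(config.seed, 1))
            rankings = {}
            for fam in THEMES:
                labels = [tagged.labels[c.id].themes[fam] for c in tagged.conversations]
                rankings[fam] = rank_features(tfidf, labels, ind, family=fam)
            lexicon = induce_lexicon(rankings, ind)
            if config.auto_refine:
                gold = {
                    fam: [tagged.labels[c.id].themes[fam] for c in tagged.conversations]
                    for fam in THEMES
                }
                lexicon = prune_uninformative(lexicon, tagged_docs, gold)
        lexicon.to_json(emit("lexicon.json"))
        lexicon.to_csv(emit("lexicon.csv"))
        finish_stage(stage, t0)

        # ---- evaluate against gold tags --------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        tagged = _tagged_theme_subset(corpus, config.induce_on_n)
        if tagged.conversations:
            evaluation = evaluate_lexicon(tagged, lexicon, config.preprocess)
            evaluation.to_csv(emit("lexicon_eval.csv"))
        else:
            manifest["warnings"].append("no gold theme labels; dictionary not evaluated")
        finish_stage(stage, t0)

        # ---- classify the full corpus ----------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        assignments = classify_docs(docs, lexicon)
        assignments_to_csv(assignments, emit("assignments.csv"))
        finish_stage(stage, t0)

        # ---- prevalence series + AR(1)+dummy tests ---------------------
        stage = "trends"
        t0 = time.perf_counter()
        series = prevalence_series(assignments, corpus, families=lexicon.family_names())
        series.to_frame().to_csv(emit("prevalence.csv"), index=False)
        fits = {}
        for fam in lexicon.family_names():
            try:
                fits[fam] = Ar1DummyModel(
                    series.prevalence(fam), series.months, config.break_month
                ).fit(lb_lags=config.lb_lags)
            except TrendDesignError as exc:
                manifest["warnings"].append(f"trend fit skipped for {fam}: {exc}")
        if fits:
            trend_report(fits).to_csv(emit("trend_report.csv"), index=False)
        finish_stage(stage, t0)

        # ---- logistic regressions + phi associations -------------------
        stage = "associations"
        t0 = time.perf_counter()
        issue_known = any(
            any(v is not None for v in ls.issues.values()) for ls in corpus.labels.values()
        )
        if issue_known:
            logit_fits = {}
            for issue in config.issues:
                design = assoc.build_design(
                    corpus, issue,
                    include_pandemic_dummy=config.pandemic_dummy,
                    break_month=config.break_month,
                )
                if design.n_dropped:
                    manifest["warnings"].append(
                        f"{issue}: dropped {design.n_dropped} conversations with unknown labels"
                    )
                logit_fits[issue] = assoc.fit_logistic(design)
            with open(emit("logit_table.txt"), "w", encoding="utf-8") as fh:
                fh.write(assoc.regression_table(logit_fits) + "\n")
            assoc.fits_to_frame(logit_fits).to_csv(emit("logit_results.csv"), index=False)

            # pairwise phi among issues and among strategies
            phi_rows = []
            labeled = [ls for ls in corpus.labels.values()]
            for group_name, names, getter in (
                ("issues", ISSUES, lambda ls, n: ls.issues[n]),
                ("strategies", STRATEGIES, lambda ls, n: ls.strategies[n]),
            ):
                for x_name, y_name in itertools.combinations(names, 2):
                    xy = [
                        (getter(ls, x_name), getter(ls, y_name))
                        for ls in labeled
                        if getter(ls, x_name) is not None and getter(ls, y_name) is not None
                    ]
                    if len(xy) < 2:
                        continue
                    xv = [p[0] for p in xy]
                    yv = [p[1] for p in xy]
                    try:
                        pa = assoc.phi_association(xv, yv)
                    except assoc.AssociationError:
                        continue
                    phi_rows.append(
                        {"group": group_name, "x": x_name, "y": y_name,
                         "phi": round(pa.phi, 6), "chi2": round(pa.chi2, 6),
                         "p": pa.p, "n": pa.n}
                    )
            if phi_rows:
                import pandas as pd

                pd.DataFrame(phi_rows).to_csv(emit("phi_associations.csv"), index=False)
        else:
            manifest["warnings"].append("no issue labels; association stage skipped")
        finish_stage(stage, t0)

        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = f"FAILED at stage {stage}: {exc}"
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        if callable(o):
            return f"<hook {getattr(o, '__name__', 'callable')}>"
        return str(o)

    echo = dataclasses.asdict(config)
    return json.loads(json.dumps(echo, default=default))
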