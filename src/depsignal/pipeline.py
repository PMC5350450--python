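"""End-to-end orchestration: lexicon -> matching -> agreement -> precision
-> frequency -> feature selection -> correlation, with a provenance manifest.

Every run writes its tables (CSV/JSON), figures (PNG), and a manifest
recording the config, the seed, package versions and a SHA-256 checksum of
each output; a rerun with the same inputs and seed is bit-identical for
the tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .agreement import GOLD, agreement_report
from .category_stats import frequency_report, heatmap, phi_matrix
from .corpus import AnnotatedCorpus, read_corpus, write_corpus
from .features import SKIPPED, lexicon_overlap, top_words
from .lexicon import Lexicon, load_lexicon
from .precision import hit_distribution, keyword_precision, plot_hit_distribution
from .synth import GeneratorConfig, corrupt_annotations, generate_corpus

logger = logging.getLogger(__name__)

ALL_STAGES = ("agreement", "precision", "frequency", "topwords", "phi")


@dataclass
class RunConfig:
    corpus_path: str | Path | None = None  # None: generate a synthetic corpus
    lexicon_path: str | Path | None = None  # None: packaged lexicon
    out_dir: str | Path = "depsignal_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    k: int = 10
    n_subsets: int = 5
    min_mentions: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: RunConfig,
    corpus: AnnotatedCorpus | None = None,
    lexicon: Lexicon | None = None,
) -> dict:
    """Run the enabled stages and write a report bundle; returns the manifest.

    A stage failure is logged, recorded in the manifest with a FAILED
    marker, and re-raised with the stage name; earlier outputs are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if lexicon is None:
        lexicon = load_lexicon(config.lexicon_path)
    if corpus is None:
        if config.corpus_path is None:
            raise ValueError("run_all needs a corpus or a corpus_path")
        corpus = read_corpus(config.corpus_path)

    manifest: dict = {
        "tool": "depsignal",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "corpus_path": str(config.corpus_path) if config.corpus_path else None,
            "lexicon_path": str(config.lexicon_path) if config.lexicon_path else None,
            "stages": list(config.stages),
            "k": config.k,
            "n_subsets": config.n_subsets,
            "min_mentions": config.min_mentions,
        },
        "n_tweets": len(corpus),
        "outputs": {},
        "skipped_stages": [s for s in ALL_STAGES if s not in config.stages],
        "timings_s": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    def run_stage(name, fn):
        if name not in config.stages:
            logger.info("stage %s skipped", name)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception:
            manifest["outputs"][name] = "FAILED"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            logger.exception("stage %s failed", name)
            raise
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, manifest["timings_s"][name])

    def stage_agreement():
        pairs_available = len([a for a in corpus.annotators() if a != GOLD]) >= 2
        if not pairs_available:
            logger.info("agreement stage: fewer than two non-gold annotators, skipping")
            manifest["skipped_stages"].append("agreement")
            return
        report = agreement_report(corpus)
        path = out / "agreement.csv"
        report.to_csv(path, na_rep="—", float_format="%.2f")
        record("agreement", path)

    def stage_precision():
        result = keyword_precision(corpus, lexicon)
        path = out / "precision.csv"
        result.frame().to_csv(path, index=False, float_format="%.4f")
        record("precision", path)
        dist = hit_distribution(result)
        dpath = out / "precision_bins.csv"
        dist.to_csv(dpath, float_format="%.6f")
        record("precision_bins", dpath)
        fig = out / "precision_bins.png"
        plot_hit_distribution(dist, fig)
        record("precision_bins_png", fig)
        manifest["keywords_not_found"] = sorted(p.render() for p in result.not_found)

    def stage_frequency():
        report = frequency_report(corpus)
        jpath = out / "frequency.json"
        jpath.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        record("frequency", jpath)
        import pandas as pd

        cpath = out / "frequency.csv"
        pd.DataFrame(
            [(c, n, p) for c, (n, p) in report.per_category.items()],
            columns=["category", "count", "pct_of_annotations"],
        ).to_csv(cpath, index=False, float_format="%.4f")
        record("frequency_csv", cpath)

    def stage_topwords():
        import pandas as pd

        rows = []
        skipped = []
        for cat in corpus.scheme.evidence_categories:
            scores = top_words(
                corpus, cat, k=config.k, n_subsets=config.n_subsets,
                seed=config.seed, min_mentions=config.min_mentions,
            )
            if scores is SKIPPED:
                skipped.append(cat)
                continue
            covered, _ = lexicon_overlap(scores, lexicon)
            for rank, ws in enumerate(scores, start=1):
                rows.append(
                    (cat, rank, ws.word, ws.avg_rank, ws.ig_bits, ws.word in covered)
                )
        path = out / "top_words.csv"
        pd.DataFrame(
            rows, columns=["category", "rank", "word", "avg_rank", "ig_bits", "in_lexicon"]
        ).to_csv(path, index=False, float_format="%.6f")
        record("topwords", path)
        manifest["topwords_skipped_categories"] = skipped

    def stage_phi():
        matrix = phi_matrix(corpus)
        wide = out / "phi_wide.csv"
        matrix.r.to_csv(wide, float_format="%.6f", na_rep="")
        record("phi_wide", wide)
        long = out / "phi_long.csv"
        matrix.pairs().to_csv(long, index=False, float_format="%.6f")
        record("phi_long", long)
        fig = out / "phi_heatmap.png"
        heatmap(matrix, fig)
        record("phi_heatmap", fig)
        manifest["phi_bin_counts"] = matrix.bin_counts()

    run_stage("agreement", stage_agreement)
    run_stage("precision", stage_precision)
    run_stage("frequency", stage_frequency)
    run_stage("topwords", stage_topwords)
    run_stage("phi", stage_phi)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def demo_generate_and_analyze(
    seed: int,
    out_dir: str | Path = "depsignal_demo",
    n_tweets: int = 10_000,
) -> dict:
    """Generate the default synthetic corpus, analyze it, and summarize
    planted-vs-estimated recovery.

    Returns the recovery summary (also written to ``recovery_summary.json``
    in the output directory, alongside the full report bundle, the corpus
    and its ground-truth sidecar).
    """
    from .category_stats import phi_matrix as _phi_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = GeneratorConfig(n_tweets=n_tweets, seed=seed)
    corpus, truth = generate_corpus(gen)
    corpus = corpus.with_annotations(
        corrupt_annotations(corpus, gen.annotators, seed=seed + 1)
    )
    write_corpus(corpus, out / "corpus.jsonl")
    truth.write(out / "ground_truth.json")

    manifest = run_all(RunConfig(out_dir=out, seed=seed), corpus=corpus)

    lexicon = load_lexicon()
    matrix = _phi_matrix(corpus)
    precisions = keyword_precision(corpus, lexicon)
    summary: dict = {"seed": seed, "n_tweets": n_tweets, "phi": [], "keywords": [], "top_words": {}}
    for a, b, target in truth.phi_targets:
        est = float(matrix.r.loc[a, b])
        summary["phi"].append(
            {"pair": [a, b], "planted": target, "estimated": round(est, 4),
             "abs_error": round(abs(est - target), 4)}
        )
    for kw, r in truth.keyword_relevance.items():
        kp = precisions.by_pattern(kw)
        summary["keywords"].append(
            {"pattern": kw, "planted_pct": 100 * r, "estimated_pct": round(kp.precision, 2),
             "tweet_hits": kp.tweet_hits}
        )
    for cat, words in truth.planted_words.items():
        scores = top_words(corpus, cat, k=10, seed=seed)
        if scores is SKIPPED:
            summary["top_words"][cat] = None
            continue
        hits = sum(1 for s in scores if s.word in words)
        summary["top_words"][cat] = {"planted_in_top10": hits}
    (out / "recovery_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    summary["manifest"] = manifest
    return summary
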