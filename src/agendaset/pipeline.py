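"""End-to-end pipeline runners with config, manifests, and stage-count logs.

Each runner executes one of the three analysis cascades (tweet dataset,
interaction dataset, mention trends), writes its outputs under
``cfg.outdir``, and records a manifest (config hash, input hashes, per-stage
counts) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import aggregation, classification, interactions, reach, trends
from .core_io import ACCOUNT_TYPES, AccountRecord, TweetRecord
from .errors import ConfigurationError
from .interactions import InteractionEvent, InteractionMatrix
from .trends import MentionSeries

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    keywords: tuple[str, ...] = ("traffic accidents", "the traffic accidents", "road accidents")
    amplification_threshold: float = 1.2
    spike_height: float = 0.3
    spike_min_separation: int = 2
    spike_window_days: int = 1
    rounding_dp: int = 2
    outdir: Path = Path("out")
    seed: int = 0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.amplification_threshold < 0:
            raise ConfigurationError("amplification_threshold must be >= 0")
        if not 0.0 < self.spike_height <= 1.0:
            raise ConfigurationError("spike_height must lie in (0, 1]")
        if self.spike_window_days < 0 or self.spike_min_separation < 0:
            raise ConfigurationError("spike windows must be >= 0")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        raw = raw or {}
        if "keywords" in raw:
            raw["keywords"] = tuple(raw["keywords"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(self.outdir)
        d["keywords"] = list(self.keywords)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    # outdir is where results land, not part of the logical configuration
    logical = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    blob = json.dumps(logical, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _hash_items(items: Sequence) -> str:
    h = hashlib.sha256()
    for item in items:
        h.update(repr(item).encode())
    return h.hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, name: str, input_hashes: dict, stage_counts: dict) -> dict:
    manifest = {
        "pipeline": name,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "input_hashes": input_hashes,
        "stage_counts": stage_counts,
    }
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    with open(cfg.outdir / f"{name}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_tweet_pipeline(
    cfg: PipelineConfig,
    tweets: Sequence[TweetRecord],
    accounts: Sequence[AccountRecord],
    sheet: classification.CodingSheet,
) -> dict:
    """Tweet-dataset cascade: regular tweets -> drop zero-retweet -> best
    tweet per user -> in-scope filter -> classify -> three share tables
    (retweet-impression rank scale, total impressions, amplification
    multipliers) -> cross-measure averages. Writes the share-table CSV.
    """
    counts: dict[str, int] = {"input_tweets": len(tweets)}
    regular = reach.select_regular_tweets(tweets)
    counts["regular_keyword_tweets"] = len(regular)
    with_rts = reach.drop_zero_retweet(regular)
    counts["with_retweets"] = len(with_rts)
    best = reach.best_tweet_per_user(with_rts)
    counts["one_per_user"] = len(best)

    in_scope_ids = {a.account_id for a in accounts if a.in_scope}
    best = [t for t in best if t.author_id in in_scope_ids]
    counts["in_scope_users"] = len(best)

    typed = {
        a.account_id: a.account_type
        for a in classification.classify_accounts(accounts, sheet, strict=False)
    }
    best = [t for t in best if typed.get(t.author_id) is not None]
    counts["typed_users"] = len(best)
    if not best:
        log.warning("tweet pipeline: no tweets survived the cascade; empty tables")
        _write_manifest(cfg, "tweet", {"tweets": _hash_items(tweets)}, counts)
        return {"tables": [], "combined": {}, "stage_counts": counts}

    scores = aggregation.rank_scale([t.retweet_impressions for t in best])
    rank_table = aggregation.type_share_table(
        [(typed[t.author_id], s) for t, s in zip(best, scores)],
        measure_name="retweet_impressions_rank_scale",
    )
    impressions_table = aggregation.type_share_table(
        [(typed[t.author_id], float(t.total_impressions)) for t in best],
        measure_name="total_impressions",
    )

    # amplification table from contributor accumulation over the full stream
    contributors = reach.contributor_records(tweets)
    amplified = reach.filter_min_amplification(contributors, cfg.amplification_threshold)
    amplified = [c for c in amplified if typed.get(c.account_id) is not None]
    counts["amplified_contributors"] = len(amplified)
    amp_table = aggregation.type_share_table(
        [(typed[c.account_id], c.amplification_multiplier) for c in amplified],
        measure_name="amplification_multipliers",
    )

    tables = [rank_table, impressions_table, amp_table]
    combined = aggregation.combine_measures(tables)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    aggregation.write_share_tables(tables, cfg.outdir / "type_shares.csv")
    _write_manifest(cfg, "tweet", {"tweets": _hash_items(tweets)}, counts)
    return {"tables": tables, "combined": combined, "stage_counts": counts}


def run_interaction_pipeline(
    cfg: PipelineConfig,
    events: Sequence[InteractionEvent],
    accounts: Sequence[AccountRecord],
    sheet: classification.CodingSheet,
) -> dict:
    """Interaction cascade: above-mean-deliveries filter -> pair extraction
    with dedup -> classify -> 4x4 matrix -> shares -> edge export."""
    counts = {"input_events": len(events)}
    kept = reach.filter_above_average_deliveries(events, deliveries=lambda e: e.deliveries)
    counts["above_mean_deliveries"] = len(kept)

    typed_accounts = classification.classify_accounts(accounts, sheet, strict=False)
    referenced = {e.source_author_id for e in kept} | {e.retweeter_id for e in kept}
    typed_accounts = [a for a in typed_accounts if a.account_id in referenced]
    matrix = interactions.build_interaction_matrix(kept, typed_accounts, unique_pairs=True)
    counts["interacting_users_pairs"] = matrix.grand_total
    row_shares, col_shares = interactions.matrix_percentages(matrix)

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    interactions.write_matrix_csv(matrix, cfg.outdir / "interaction_matrix.csv")
    interactions.write_edge_list_csv(matrix, cfg.outdir / "interaction_edges.csv")
    _write_manifest(cfg, "interaction", {"events": _hash_items(events)}, counts)
    return {
        "matrix": matrix,
        "row_shares": row_shares,
        "col_shares": col_shares,
        "stage_counts": counts,
    }


def run_trends_pipeline(
    cfg: PipelineConfig, series_a: MentionSeries, series_b: MentionSeries
) -> dict:
    """Normalize both channels, detect spikes, match them, write the
    plot-ready normalized CSVs and the match report."""
    norm_a = trends.normalize_series(series_a)
    norm_b = trends.normalize_series(series_b)
    spikes_a = trends.detect_spikes(norm_a, cfg.spike_height, cfg.spike_min_separation)
    spikes_b = trends.detect_spikes(norm_b, cfg.spike_height, cfg.spike_min_separation)
    report = trends.match_spikes(spikes_a, spikes_b, cfg.spike_window_days)
    counts = {
        "days_a": len(norm_a.counts),
        "days_b": len(norm_b.counts),
        "spikes_a": len(spikes_a),
        "spikes_b": len(spikes_b),
        "n_matched": report.n_matched,
    }
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    norm_a.to_daily_csv(cfg.outdir / f"trend_{norm_a.channel}.csv")
    norm_b.to_daily_csv(cfg.outdir / f"trend_{norm_b.channel}.csv")
    with open(cfg.outdir / "spike_match.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "spikes_a": list(report.spikes_a),
                "spikes_b": list(report.spikes_b),
                "matches": [list(m) for m in report.matches],
                "window_days": report.window_days,
                "n_matched": report.n_matched,
            },
            fh,
            indent=2,
        )
    _write_manifest(
        cfg,
        "trends",
        {"series_a": _hash_items(norm_a.counts), "series_b": _hash_items(norm_b.counts)},
        counts,
    )
    return {"report": report, "stage_counts": counts}
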