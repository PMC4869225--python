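# agendaset

Analytics for agenda-setting on social media: given a keyword-tracked tweet
stream, the package computes reach metrics (deliveries, retweet impressions,
total impressions, amplification multipliers), applies the documented filter
cascades, classifies accounts into four types (individual, organizational,
media, policy) with inter-rater reliability checking, aggregates per-type
influence shares, builds the 4x4 source/target retweet-interaction matrix,
and compares daily keyword-mention trends across two channels by matching
spikes. A seeded synthetic cascade generator makes every stage testable
offline with exact ground truth.

## CLI

```bash
# generate a synthetic dataset with known ground truth
agendaset simulate --outdir data/ --seed 1 --n-accounts 2000 --days 90

# tweet-dataset cascade -> per-type share tables + cross-measure averages
agendaset tweet-pipeline --tweets data/tweets.csv --accounts data/accounts.csv \
    --coding data/coding_truth.csv --outdir out/

# contributor filter (amplification multiplier >= 1.2) -> amplification shares
agendaset contributor-pipeline --contributors data/contributors.csv \
    --coding data/coding_truth.csv --outdir out/

# source/target interaction matrix + edge list
agendaset interaction-pipeline --tweets data/tweets.csv --accounts data/accounts.csv \
    --coding data/coding_truth.csv --outdir out/

# mention-trend comparison (normalize, detect spikes, match within +/-1 day)
agendaset trends --series-a data/mentions_twitter.csv \
    --series-b data/mentions_newspaper.csv --outdir out/

# inter-rater reliability between two coding sheets
agendaset kappa --sheet-a coder1.csv --sheet-b coder2.csv
```

Thresholds (amplification cut-off, spike height/separation/window) can be set
in a YAML/JSON config passed via `--config` and overridden by flags. Every
pipeline writes a manifest (config hash, input hashes, per-stage counts) next
to its outputs, and `-v` logs each filter's input/output sizes.

## Method notes

- **Amplification multiplier** = ((total exposure − impressions) /
  impressions) + 1; contributors below 1.2 are filtered out (boundary kept).
- **Filter cascade** for the tweet dataset: keyword-matched original tweets →
  drop zero-retweet tweets → best tweet (highest retweet impressions) per
  user → in-scope filter → classification → share tables for the
  retweet-impression rank scale, total impressions, and amplification
  multipliers → unweighted cross-measure average.
- **Interaction matrix** rows are the source of influence (author of the
  retweeted message), columns the target (the retweeter); cells count unique
  user pairs after the above-mean-deliveries filter, self-retweets excluded.
- **Kappa benchmark** (Fleiss): < 0.40 poor, 0.40–0.75 intermediate-good,
  > 0.75 excellent.
- Keyword matching is literal, case-sensitive substring matching; percentage
  shares are rounded half-up to 2 decimals.

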