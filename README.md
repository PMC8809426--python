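# trapid

Analysis toolkit for assessing facial photo-identification of uniformly
pelaged carnivores from camera-trap imagery. The pipeline covers:

- **Detection events** — chaining raw photo records into independent
  detection events (>30 min gap rule), with per-event face-capture,
  behavior, night/day (astronomical twilight via a built-in NOAA-style
  solar ephemeris), image-type and face-resolution attributes.
- **Contingency statistics** — Pearson chi-squared tests (no continuity
  correction) and face-capture rate summaries comparing attention-caller
  (ACD) sites against conventional sites.
- **Identity ratings** — bookkeeping for multi-rater pairwise same/different
  verdicts: pair enumeration, per-rater identity partitions (connected
  components of "same" graphs), contradiction detection, and singleton
  adjustment (flipping lone dissents to the consensus).
- **Agreement statistics** — Fleiss' kappa with large-sample confidence
  intervals, either/or/both attribute-subset kappas, and Spearman rank
  correlation between event attributes.
- **Detection-rate GLMM** — Poisson mixed model of daily detection counts
  with independent Gaussian random intercepts (site/season/year) fit by a
  Laplace approximation, backward stepwise selection by likelihood-ratio
  test, AIC ranking, type-III Wald tests under sum contrasts, and
  overdispersion / zero-inflation diagnostics.
- **Synthetic data** — generators for every input with known ground truth:
  site-day detection histories from a Poisson log-linear truth, latent
  individual identities with attributes, multi-rater verdicts under an
  attribute-aware confusion model, and photo streams that regroup exactly
  to their source events.

## Command line

```sh
# simulate inputs with known truth
trapid simulate photos  --seed 17 --out sim/
trapid simulate ratings --seed 17 --out sim/
trapid simulate history --seed 17 --out sim/

# analysis stages
trapid events --photos sim/photos.csv --sites sites.csv --gap-minutes 30 --out events.csv
trapid contingency --events events.csv --sites sites.csv --out contingency.csv
trapid agreement kappa --ratings sim/ratings.csv --level 0.95 --out kappa.csv
trapid agreement partitions --ratings sim/ratings.csv --out partitions/
trapid glmm --data sim/history.csv --full-model "deploy*acd + lure + scrape" \
            --random site --random season --random year --select backward --out glmm/

# everything at once (synthetic inputs unless a config provides files)
trapid run-all --seed 17 --out results/
```

All interchange is delimited text (CSV, ISO-8601 timestamps). Readers are
strict by default; `--lenient` normalizes cosmetic variation.

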