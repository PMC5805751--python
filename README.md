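# repgen

Generative-probabilistic analysis of immune receptor (TCR/BCR) repertoires.

`repgen` models V(D)J recombination as a Bayesian network of stochastic
events — germline gene choices, end deletions (negative values encode retained
P-nucleotides), non-templated junction insertions whose nucleotide identities
follow dinucleotide Markov chains — plus a per-nucleotide error or
context-dependent somatic-hypermutation process.  On top of this model it
provides:

* **analysis** — for each read, enumerate the recombination(+mutation)
  scenarios consistent with it, rank them by likelihood
  `P_scenario = P_recomb x P_err`, and compute the read probability `P_read`
  and generation probability `P_gen` (for mutated reads, a posterior-weighted
  geometric mean over candidate ancestral sequences);
* **learning** — fit all model parameters from unique reads by
  expectation-maximization with exact posterior event marginals (computed by
  forward–backward over a chain factorization of the scenario space, i.e.
  without enumeration or pruning noise);
* **generation** — sample synthetic repertoires with ground-truth scenarios,
  sequencing errors or PWM-driven hypermutations, J-anchored read truncation,
  and rejection filters (out-of-frame selection, CDR3-length matching);
* **hypermutation models** — additive 7-mer PWMs with a logistic link (kept in
  the zero-sum gauge, so the overall rate `mu` is the geometric-mean mutation
  odds) and non-additive n-mer rate tables, plus posterior mutation profiles
  and the spatial co-localization index `g(r)`;
* **evaluation** — exact Kullback–Leibler divergence between models with a
  per-feature chain-rule decomposition, true-scenario rank statistics
  (degeneracy analysis), and tandem-D detection.

Small toy fixtures and two realistic synthetic models (a TRB-like 8V×2D×6J
locus with the D2–J1 pairing exclusion, and an IGH-like 6V×3D×4J locus with a
7-mer hypermutation PWM set) are bundled as plain text under
`src/repgen/data/` and regenerated by `scripts/make_bundled_models.py`.

## Command line

```bash
# sample 1000 60-bp reads with ground truth from the bundled TRB-like model
repgen generate --model src/repgen/data/model_trb_synth.txt \
    --n 1000 --seed 7 --read-length 60 --outdir out/gen

# re-learn the model from those reads by EM
repgen learn --model src/repgen/data/model_trb_synth.txt \
    --reads out/gen/reads.fasta --outdir out/learn --max-iter 6

# ranked scenarios, P_read and P_gen per read
repgen analyze --model out/learn/model.txt \
    --reads out/gen/reads.fasta --outdir out/ana

# KL divergence between models + rank statistics vs the ground truth
repgen evaluate --model-a src/repgen/data/model_trb_synth.txt \
    --model-b out/learn/model.txt \
    --truth out/gen/truth.tsv --scenarios out/ana/scenarios.csv \
    --outdir out/ev
```

Every run writes a `manifest.json` (config echo, seed, version, input
checksums) and a `run.log` under `--outdir`; outputs use fixed filenames
(`reads.fasta`, `truth.tsv`, `model.txt`, `scenarios.csv`, `pgen.csv`,
`trajectory.csv`, `metrics.json`).  Model files are human-readable text
(`@structure` / `@cpt` / `@error` / `@shm` sections) and round-trip
bit-exactly.

## Library example

```python
from repgen.cli_io.bundled import bundled_model
from repgen.generation import generate_batch, ReadConfig
from repgen.inference import em_learn, EMConfig
from repgen.scenarios import annotate, pgen

model, _ = bundled_model("trb_synth")
recs = generate_batch(model, 500, seed=1, read_cfg=ReadConfig(length=60))
res = annotate(recs[0].read, model)
print(res.ranked_scenarios[0], res.p_read)
print(pgen(recs[0].ancestor, model, anchor="3p"))
```
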