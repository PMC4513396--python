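# kmermask

Self-training de novo repeat detection and genome masking.

Repeats — transposable elements, tandem repeats, low-complexity stretches —
make up large fractions of most genomes, and because they are species
specific, a newly sequenced genome cannot be annotated from a repeat
library. `kmermask` finds repeats using nothing but the repetitive nature
of repeats: it labels its own training data and trains itself on each input
genome, with no alignment step, no repeat database and no external tools.

## Who it is for

Anyone who needs to soft-mask an assembled or unassembled genome before
annotation, alignment or gene prediction, and anyone studying repeat
content without a curated library. Input is FASTA; output is masked FASTA
plus BED intervals.

## The method

1. **Scoring.** Every word of length *k* is indexed by its quaternary
   number (A,C,G,T → 0,1,2,3; consecutive indices by Horner's rule) and
   counted genome-wide in a dense 4^k table. Counts are adjusted against a
   Markov chain of order *o* (default 6) trained on the same genome:

   * a word observed once or twice scores 0;
   * a word whose observed count does not exceed the chain's expected
     count scores 0;
   * otherwise it scores *observed − expected*.

   The score of a nucleotide is the adjusted count of the word starting
   there. The adjustment cancels compositional bias and low-copy
   duplication (ohnologous genes in a polyploid genome have observed ≈
   expected), so single-copy and coding sequence scores ~0 while genuine
   repetition stands out. By default *k* ≈ log₄(genome size), which puts
   the chance expectation of a random word near one occurrence.

2. **Labeling.** The score track *s* is smoothed with a Gaussian mask
   (width ≈ 7σ, default 40 bp): *s̄ᵢ* = Σⱼ sⱼ mₚ ⁄ Σₚ mₚ. Local maxima of
   *s̄* are found with the discrete second-derivative test over a window
   *w* = 10 ( f′(i) = Σ_{i−w..i−1} s̄ − Σ_{i+1..i+w} s̄ ; f″(i) = both sums −
   2w·s̄ᵢ ): a maximum lies where the sign of f′ flips and f″ < 0. Runs of
   s̄ ≥ t (default t = 2) containing at least one maximum become candidate
   repetitive regions; long runs below t become potential non-repetitive
   regions.

3. **Self-training.** A two-track hidden Markov model is trained on those
   auto-generated labels. Each score collapses to a level,
   output(s) = ⌈log_t s⌉ for s > 0 and 0 otherwise, and every level owns a
   repeat state and a non-repeat state, so the state count is twice the
   number of levels. Output probabilities are 1 (a state emits exactly its
   level); priors and transitions are counted from the labeled regions.

4. **Scanning.** Viterbi decoding of the score track yields the final
   segmentation; runs of repeat states, extended by *k*−1 bp to cover the
   tail of the last repeated word, are the final repeats. The trained
   model consolidates its own fragmented training labels: the final
   regions are fewer and cover the true repeats at least as completely as
   the candidates did.

The whole pipeline is deterministic and linear-time in the genome size.

## Worked example

Simulate a 200 kb genome (order-3 Markov background, a 500 bp repeat
family at 5 % divergence, tandem arrays, unique "exons"), detect, and
evaluate against the planted truth:

```python
import kmermask as km

spec = km.default_spec(seed=1, genome_length=200_000, scale=0.2)
seqs, truth, exons = km.simulate(spec)
result = km.detect(seqs)
print("k =", result.k, "| states =", result.model.n_states)
print("candidates:", len(result.candidates), "| final repeats:", len(result.repeats))
print("SN_all  = %.1f %%" % km.sensitivity(result.repeats, truth))
print("SP_exon = %.1f %%" % km.specificity_exon(result.repeats, exons))
print("PP      = %.1f %%" % km.percentage_predicted(result.repeats, seqs))
```

prints

```
k = 9 | states = 12
candidates: 155 | final repeats: 52
SN_all  = 99.2 %
SP_exon = 100.0 %
PP      = 12.6 %
```

SN_all is the base-level share of planted repeats recovered; SP_exon the
share of exonic bases avoided; PP the fraction of the genome masked (the
planted density here is ~12.5 %, so 12.6 % predicted means the detector is
calling almost exactly the planted material). Note how 155 fragmented
candidate labels consolidate into 52 final regions after self-training.

The same run from the shell:

```sh
kmermask simulate --seed 1 --length 200000 -o sim/
kmermask mask sim/genome.fa -o out/            # masked.fa + repeats.bed
kmermask evaluate --pred out/repeats.bed --truth sim/repeats.bed \
    --exons sim/exons.bed --genome sim/genome.fa
```

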