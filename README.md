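# pwcom

Quality assessment (QA) for protein structure prediction: given a *decoy
set* — many candidate 3D models of one target protein — rank the decoys by
how close they are to the (unknown) native structure and pick the best one.

`pwcom` implements a pairwise two-stage combination score. Consensus methods
such as consensus GDT (CGDT) rate each decoy by its average structural
similarity to the rest of the pool and work well when good models form a
majority cluster; single-model scoring functions (knowledge-based
potentials) see information consensus cannot, but are noisy. The pairwise
combination gets the best of both.

## Method

Each decoy *i* carries a five-score feature vector
*f(i) = (S₁, S₂, S₃, PSPS, CGDT)*:

* **CGDT** — mean GDT-TS of the decoy to every other member of the set,
  where GDT-TS is the mean over cutoffs {1, 2, 4, 8} Å of the largest
  fraction of Cα atoms superposable within the cutoff;
* **PSPS** (Position Specific Probability Sum) — a consensus score in
  structure-code space: each residue window of four consecutive Cα atoms is
  mapped to an angle triplet (θ₁, τ, θ₂) (bend, dihedral, bend), assigned to
  one of 17 Gaussian-mixture states, and a decoy scores
  `PSPS(i) = Σ_pos f(c_pos(i), pos)` — the summed frequency, over the decoy
  pool, of its own state at each position (bounded by L−3);
* **S₁–S₃** — any single-model scores supplied as tables (e.g. OPUS-Ca, RW,
  DDFire energies), or the built-in Cα distance-bin log-odds stand-in
  potential.

For every decoy pair the difference *f(i) − f(j)* is fed to two small neural
classifiers (5 inputs → 3 sigmoid hidden units → sigmoid output) in
sequence: **model 1** predicts whether the pair differs significantly in
true quality (|ΔGDT| > 0.025); if yes, **model 2** predicts the winner
(pairs with |ΔGDT| < 0.01 are excluded from its training data). A decoy's
final score is its number of wins over the whole pairwise tournament.
Training and evaluation are leave-one-out at target level: each decoy set is
scored by models trained on all other sets' pairs.

Selection quality is summarised the standard way: **GDT1** (true GDT of the
top-ranked decoy), **avgGDT5** (mean true GDT of the top five), and
Pearson/Spearman correlation of the score with true GDT.

## Worked example

Everything runs on synthetic decoy sets (native-like Cα traces plus
chain-smoothed coordinate noise), so no downloads are needed:

```bash
pwcom synth -l 40 -n 12 --seed 0 --out demo/t0
pwcom synth -l 40 -n 12 --seed 1 --out demo/t1
cat > demo/targets.yaml <<EOF
- {decoys: demo/t0/decoys, native: demo/t0/native.pdb}
- {decoys: demo/t1/decoys, native: demo/t1/native.pdb}
EOF
pwcom train --targets demo/targets.yaml --seed 1 --out demo/models.json
pwcom score --decoys demo/t1/decoys --models demo/models.json --out demo/pwcom.tsv
pwcom eval --scores PWCom=demo/pwcom.tsv --truth demo/t1/true_gdt.tsv --out demo/metrics.tsv
cat demo/metrics.tsv
```

prints

```
score	GDT1	avgGDT5	Pearson	Spearman
PWCom	0.9563	0.8250	0.9924	0.9947
```

meaning: on target `t1` the decoy ranked first by the pairwise score has
true GDT-TS 0.956 (an excellent pick), the top five average 0.825, and the
winning counts correlate with true quality at Spearman 0.99. (Exact numbers
depend on the seeds; this is the output of the commands above as written.)

The same functionality is available as a library:

```python
from pwcom import SynthConfig, synth_native, synth_decoys, build_panel, loo_train_eval
```

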