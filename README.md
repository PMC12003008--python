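# alarmtrie

Positional information-gain analysis of labeled call sequences.

Many animals produce alarm calls in structured sequences, and a central
question in animal communication is whether listeners can predict the
call-eliciting event (the *referent*) from only the first few calls — the way
human listeners disambiguate words incrementally from their initial sounds.
`alarmtrie` quantifies this *incremental disambiguation* for corpora of call
sequences over a small alphabet (the motivating system is the olive colobus
monkey, whose repertoire has just two call types, `A` and `B`, combined in
sequences elicited by eagles, leopards, and falling trees). The package is
for bioacousticians and comparative linguists who have a table of sequences
labeled with their eliciting stimulus class and want to know *at which call
position* the referent becomes predictable.

## Model

Sequences are arranged in a **prefix trie** over the extended alphabet
(call symbols plus an absorbing end symbol `∅`): the depth-*t* nodes are the
distinct extended *t*-prefixes, and because `∅` absorbs, they partition the
whole corpus at every position. Stimulus classes *y* (out of *K*) are
unbalanced in elicitation studies, so each receives the inverse-frequency
weight

```
w_y = 1 / (K · N_y),          Σ_y w_y N_y = 1,
```

giving every class prior probability 1/K. With node masses
Pr(s) = Σ_y w_y c_y(s) and conditional class probabilities
p_y(s) = w_y c_y(s) / Pr(s), the package tracks three per-position indices:

```
H(t) = Σ_s Pr(s) · [ −Σ_y p_y(s) log_K p_y(s) ]     normalized entropy ∈ [0, 1]
D(t|t−1) = H(t−1) − H(t)                             Kullback-Leibler gain ≥ 0
J(t) = Σ_s Pr(s) · max_y p_y(s)                      prediction gain ∈ [1/K, 1]
```

Before any call, H(0) = 1 and J(0) = 1/K. Whether position *t* adds
information beyond position *t−1* is tested against a **permutation null**:
class labels are shuffled among sequences sharing the same extended
(*t−1*)-prefix — which leaves every statistic up to position *t−1* exactly
unchanged — and the 2.5%/97.5% quantiles of the permuted index form a 95%
interval; an observed value outside it flags the position as informative.

A seeded synthetic-corpus generator (`alarmtrie.synthetic`) draws whole
sequences from class-conditional finite-support distributions, so every
expected statistic has a closed form; its `colobus_preset()` emulates an
olive colobus elicitation corpus (class sizes 39 eagle / 79 falling tree /
166 leopard, eagle sequences A-initial, leopard sequences built on 'BA',
falling-tree sequences on 'BAA').

## Worked example

A four-sequence corpus (`AA`→eagle, `AB`→eagle, `BA`→leopard,
`BAA`→falling tree):

```sh
printf 'sequence\tlabel\nAA\tE\nAB\tE\nBA\tL\nBAA\tT\n' > tiny.tsv
alarmtrie analyze tiny.tsv --max-depth 3 --out tiny_profile.tsv
cat tiny_profile.tsv
```

```
t	H	D	J	...
0	0.9999999999999998	0.0	0.3333333333333333
1	0.42061983571430495	0.5793801642856948	0.6666666666666666
2	0.42061983571430495	0.0	0.6666666666666666
3	0.0	0.42061983571430495	1.0
```

Reading: before any call the three classes are equally likely (H = 1,
J = 1/3). The first call splits eagle (`A...`) from non-eagle (`B...`):
entropy drops to (2/3)·log₃2 ≈ 0.4206 (a KL gain of 0.5794) and a guess is
now right two times in three. The second call adds nothing (D = 0). The
third position — where `BA∅`, `BAA`, and the `A`-initial forms part ways —
resolves the referent completely (H = 0, J = 1).

The same pipeline scales to full corpora:

```sh
alarmtrie simulate --preset colobus --seed 1 --out corpus.tsv   # 284 sequences
alarmtrie permtest corpus.tsv --n-perm 10000 --seed 1 --out profile.tsv
alarmtrie plot profile.tsv --out profile.png
```

`permtest` appends the null intervals and significance flags per position;
`analyze --dot trie.dot` additionally exports a Graphviz rendering of the
trie with nodes colored by their weighted class distribution (red = leopard,
green = falling tree, blue = eagle; gray = ambiguous) and edge thickness
proportional to transition probability.

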