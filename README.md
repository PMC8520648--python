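# ordbench

Benchmarking statistical tests for **ordinal trial outcomes** in vascular
prevention trials.

Most cardiovascular prevention trials grade their outcome events by
severity — a stroke can be a TIA, a non-disabling stroke, a disabling
stroke, or fatal — and then throw that information away by analysing the
binary "any event vs none" endpoint. `ordbench` provides the machinery to
quantify what that costs:

* a **trial model** for participants, severity scales, and two-arm
  comparator datasets (multi-arm trials expand into several comparisons);
* a **synthetic data generator** with an exactly proportional-odds
  treatment effect, baseline covariates that shift event occurrence, and
  event times for the survival methods;
* a **battery of fifteen significance tests** spanning binary (chi-square,
  adjusted logistic, Cox), ordinal (ordinal logistic regression,
  Mann–Whitney U, Cochran–Armitage, win ratio, bootstrap mean-rank) and
  score-based (t-test, linear model) approaches;
* a **comparison engine** that ranks the methods' p-values across many
  datasets, tests agreement with a tie-adjusted Friedman test, groups
  statistically indistinguishable methods with Duncan's multiple range
  test, and checks bootstrap type-I error on neutral data;
* **sample-size formulas** (binary proportions, Whitehead
  proportional-odds, Noether/Mann–Whitney, t-test) with
  ordinal-vs-binary multiplier reports. On the packaged 13-trial
  reference table the median ordinal multiplier is **0.66** and the
  median rank-based multiplier **0.18** — i.e. ordinal analysis needs
  about a third fewer participants, and rank-based tests about 82% fewer,
  than the binary comparison for the same power.

The headline finding the package reproduces: ordinal methods
(Mann–Whitney U, ordinal logistic regression) are consistently the most
sensitive, the fatal-only chi-square is consistently the least, and the
type-I error of the leading methods is nominal (~5%) on neutral data.

See [docs/methods.md](docs/methods.md) for the statistical details and
definitions, and `/root/notes/decisions.md` (outside the package) for the
design-decision ledger.

## Worked example

Simulate six comparator trials on the 4-level `strokeTIA4` scale
(none / TIA / non-fatal stroke / fatal stroke) with a common-odds-ratio
benefit of exp(−0.22) ≈ 0.80, run the battery on each, and compare:

```sh
for i in 0 1 2 3 4 5; do
  ordbench simulate --scale strokeTIA4 --n-per-arm 2000 --log-or -0.22 \
      --seed 7 --stream $i --id trial$i --out trial$i.csv
  ordbench battery --data trial$i.csv --scale strokeTIA4 --id trial$i \
      --seed 7 --out battery$i.csv
done
ordbench compare battery0.csv battery1.csv battery2.csv \
                 battery3.csv battery4.csv battery5.csv
```

Actual output (deterministic for these seeds):

```text
6 datasets (Friedman p=0.000195)
rating  method   mean rank  letters
     1  OLR_adj *     4.17  A
     2  BLR_adj *     4.50  AB
     3  MWU     *     5.33  AB
     4  CPH_adj *     5.67  ABC
     5  OLR     *     6.50  ABC
     6  MLR_adj *     6.83  ABC
     7  CSB     *     7.17  ABC
     8  MT      *     7.17  ABC
     9  WR      *     7.50  ABC
    10  TT      *     8.33  ABC
    11  CPH     *     8.67  ABC
    12  CAT           9.00  BC
    13  BS           10.17  C
    14  CSO          14.33  D
    15  CSF          14.67  D
```

Methods are rated by mean rank of their p-values across the six trials
(1 = most sensitive); `*` marks the Duncan top group (methods sharing a
letter with the rating-1 method). Even on six datasets the published
qualitative picture appears: adjusted ordinal regression and Mann–Whitney
lead, the fatal-only and unordered-ordinal chi-squares trail decisively.

A single battery run prints to CSV; for `trial0.csv` the fifteen p-values
include (via `ordbench battery --data trial0.csv --scale strokeTIA4`):
MWU 0.008, OLR 0.008, adjusted OLR 0.009, any-event chi-square 0.008,
fatal-only chi-square 0.272 — the severity information is worth real
significance at this effect size.

Check type-I error on a packaged neutral fixture (dummy arm, zero effect):

```sh
ordbench type1 --data fixtures/null_stroke3.csv --scale stroke3 \
    --methods MWU,OLR --b 200 --seed 4
```

```text
method  significant   B  alpha
   MWU            8 200   0.05
   OLR            8 200   0.05
```

8/200 = 4% significant resamples — nominal. Print the packaged reference
sample-size table with multipliers:

```sh
ordbench samplesize --table6
```

```text
 dataset  n_binary  n_ordinal  n_mwu  n_ttest  mult_binary  mult_ordinal  mult_mwu  mult_ttest
       1      4528       4052   1194     1196            1         0.890     0.260       0.260
       2     17986      11970   3326     3904            1         0.670     0.180       0.220
       3     15292      10072   2744     2828            1         0.660     0.180       0.180
       4      5436       2382    704      898            1         0.440     0.130       0.170
       5     25090       8666   2426     3362            1         0.350     0.097       0.130
       6     30450      10164   2958     5070            1         0.330     0.097       0.170
      13     13510      12610   3806     3754            1         0.930     0.280       0.280
      18     23090      22110   6486     7194            1         0.960     0.280       0.310
      30     15934       1582    442      566            1         0.099     0.028       0.036
      31      6934       1952    608      802            1         0.280     0.088       0.120
      32    115114      63792  17482    19952            1         0.550     0.150       0.170
      33     15198      10862   3388     3450            1         0.710     0.220       0.230
      55     37646      37456  10924    12186            1         0.990     0.290       0.320
```

An entire multi-scenario study (simulation → batteries → ratings →
subgroup ratings → sample sizes → type-I assessment → manifest) runs from
one YAML config:

```sh
ordbench study --config fixtures/study_example.yaml --out study_out
```

The Python API mirrors the CLI: `ordbench.simulate.simulate_comparator`,
`ordbench.battery.run_battery`, `ordbench.compare.compare_methods`,
`ordbench.samplesize.multiplier_report`, `ordbench.study.run_study`.

## Reproduction

Everything is deterministic given `(seed, stream)`
(`numpy.random.SeedSequence([seed, stream])` throughout; no global RNG).

* **Test suite** (≈ 110 unit/property tests plus 5 acceptance tests, one
  per acceptance criterion; the full run takes 5–10 minutes, dominated by
  the 100-replicate rating-replication criterion):

  ```sh
  pytest -q
  ```

* **Acceptance target** (bootstrap type-I count for Mann–Whitney on a
  neutral 2000-per-arm 3-level dataset; calibrated band 33–68 of 1000):

  ```sh
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  # -> {"t5": {"value": 48, "n": 1000}}   (~25 s)
  ```

* **Fixtures** under `fixtures/` (effect/null/rare datasets, a custom
  scale YAML, a study config) regenerate byte-identically with:

  ```sh
  python scripts/make_fixtures.py
  ```

## Caveats

* The generator is exactly proportional-odds with covariates acting on
  event occurrence only; it is a best case for the model-based ordinal
  methods. The rank-based methods need no such assumption.
* The Noether sample-size formula assumes continuous responses; on
  heavily tied ordinal data its N is conservative (simulated power can
  reach 1.0). This is a property of the published formula, not a bug —
  see docs/methods.md §5.
* Methods that cannot run on a dataset (no fatal events, constant
  outcome, …) return a degenerate p = 1 result and are ranked last rather
  than dropped, which penalises fragile methods in the ratings by design.
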