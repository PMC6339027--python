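# Methods

## Model and assumptions

`ppsdt` trains one categorical decision tree by information gain over data
horizontally partitioned across two or more hospitals. The threat model is
**honest-but-curious**: every party follows the protocol but may try to learn
extra information from the messages it sees; collusion between parties is out
of scope, as are malicious deviations, dropouts, and message authentication.

Three roles:

* the **Trusted Authority** acts only at setup. It generates one Paillier
  pair shared by all hospitals and the cloud's RSA pair, and distributes
  them. The cloud receives the Paillier *public* key only — it can add
  ciphertexts but never decrypt them (a test monkeypatches Paillier
  decryption to raise inside the cloud's aggregation path).
* **hospitals** hold records and the shared Paillier pair;
* the **cloud** aggregates ciphertexts and schedules rounds.

Because all hospitals hold the same Paillier key, a hospital that intercepts
another's ciphertexts could decrypt them. Each hospital therefore adds a
secret per-session nonce `z` to every count before encrypting, and sends `z`
to the cloud sealed under the cloud's RSA key. The cloud removes the blinding
homomorphically (multiplying by `g^(−z)`) before summing, so the pooled
matrices it broadcasts decrypt to exact pooled counts. Note the inherent
asymmetry: the *returned* aggregates are decryptable by any key holder — that
is the intended functionality (every hospital needs the pooled counts), so
the nonce protects only matrices in transit from hospital to cloud. The
protocol deliberately reveals pooled aggregate frequencies and the pooled
dataset size to all hospitals; it does not attempt differential privacy on
those aggregates.

## Split criterion and determinism

Splits maximize plain information gain (no gain ratio, no pruning, no
continuous attributes — the method is C4.5-flavoured ID3 on categorical
data). Every hospital must reach bit-identical decisions, so all potentially
ambiguous choices are fixed:

* equal-gain ties go to the attribute earliest in schema order;
* a pure partition closes as a leaf of its class;
* when no attributes remain, the majority class wins, ties to the lowest
  class index;
* an empty child partition closes with its parent partition's majority class.

Child outcomes are read directly off the rows of the chosen attribute's
pooled matrix (a row *is* the child partition's class-count vector), so leaf
children cost no extra protocol round; only impure children with remaining
attributes trigger another encrypt–aggregate–decrypt exchange. Partitions are
expanded depth-first, child values in schema order. Any cross-hospital
disagreement on a round decision aborts the session — it should be
impossible and acts as a correctness tripwire.

The package also ships `c45.build_tree_plaintext`, an independent single-site
recursion over raw records with the same determinism rules. The central
correctness property — asserted over 50 seeded federations of 2–5 hospitals
and pooled sizes 10–120 — is node-for-node equality of the protocol tree and
this reference tree.

## Cryptographic choices

* **Paillier**: generator `g = n+1` by default, for which
  `g^m mod n² = 1 + m·n` (one multiplication); arbitrary generators remain
  supported and the invertibility of `L(g^λ mod n²)` is always verified at
  keygen. Primes come from 40-round Miller–Rabin (error ≤ 4⁻⁴⁰) on
  equal-bit-length candidates with distinct `p ≠ q`. Plaintexts are
  non-negative counts; negative shifts enter only through the mod-n reduction
  in `h_add_const`. The default modulus is 2048 bits; tests use 512-bit keys,
  which are far too small for real deployments but preserve every algebraic
  property. Ciphertexts travel as lowercase hex; key files are JSON with hex
  fields, private keys written mode 0600.
* **Nonce envelope**: randomized OAEP (SHA-1 hash + MGF1) rather than
  textbook RSA — a deterministic encryption of a 32-bit nonce would be
  invertible by table lookup, defeating the blinding. SHA-1 keeps the OAEP
  minimum modulus at 512 bits so test keys stay fast; the padding role here
  needs randomization, not collision resistance. Any padding inconsistency on
  opening raises a tamper error rather than returning a wrong value.
* **Nonce range**: `z` uniform in `[1, 2³²)` (configurable down via
  `nonce_bits`), one nonce per hospital per session. Session setup rejects
  configurations where `max count + z` could reach the Paillier modulus.
* **Randomness**: every keygen, nonce draw, and encryption accepts a seeded
  RNG for reproducible runs; without a seed, OS entropy is used. A whole
  training session is reproducible from one master seed.

## Synthetic data generator

The generator emulates an acute-urinary-inflammation screening table: five
binary symptom attributes (Nausea, Lumbar pain, Urine pushing, Micturition
pains, Burning of urethra) and four diagnosis classes (0 none, 1 nephritis,
2 bladder inflammation, 3 both). Attribute values are drawn uniformly; the
default class rule is deterministic — bladder inflammation iff `UP=1 ∧ MP=1`,
nephritis iff `LP=1 ∧ N=1` — with an optional label-noise rate that flips a
class to a uniformly chosen different one. A class-conditional mode (class
prior + per-attribute Bernoulli probabilities) supports distributional tests.
Hospitals receive consecutive blocks of one pooled sample, so the pooled
dataset depends only on the seed, not on the number of hospitals.

What the generator does *not* emulate: attribute correlations of real
screening data, class imbalance of real incidence rates, missing values
(rejected at load), and continuous vitals such as temperature. Passing the
oracle-equivalence sweep therefore demonstrates protocol correctness — the
encryption layers change nothing about the trained tree — not clinical
validity of the resulting classifier.

The 22-record worked-example aggregate (`dataset.nausea_fixture`) is the
pooled Nausea matrix `[[8,3,5,0],[0,2,0,4]]` with class totals (8,5,5,4); it
is a fixed reference aggregate, not generator output. Double-precision
evaluation gives entropy 1.9495, attribute entropy 1.3248, gain 0.6247 bits;
published hand calculations for this example round intermediates and quote
1.949 / 1.3252 / 0.6238, which is why the worked-example tests use a ±0.005
band.

## Numerical and scaling notes

* All entropy arithmetic is double precision, log base 2, no intermediate
  rounding; `0·log₂0 ≡ 0`; information gain is clamped-checked against a
  −10⁻⁹ floating-point guard (it is analytically non-negative).
* The per-round workload is `attributes × classes × values` matrix cells per
  hospital (`protocol.complexity`); with ragged domains the maximum domain
  size is used and a warning emitted. Only attributes not yet on the split
  path are counted and shipped each round.
* Test problem sizes — 512-bit keys, federations of 2–5 hospitals, pooled
  10–120 records — keep the full suite in a few minutes of CPU while
  exercising every protocol path; all properties are size-agnostic.
* Benchmark timings (`ppsdt benchmark`) are reported as CSV for plotting and
  asserted only for the qualitative trend that larger moduli cost more;
  absolute times are hardware-dependent.

## Known limitations

* Security is semi-honest only: no MACs, no collusion resistance, no
  threshold decryption, no side-channel hardening, CPA-level Paillier.
* The shared-key design means any hospital can decrypt the broadcast pooled
  matrices (by design) and the nonce is the sole protection for in-transit
  hospital submissions.
* Categorical attributes only; no missing-data handling, pruning, or
  ensembles.
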