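# ppsdt — privacy-preserving single decision tree training

Hospitals that each hold part of a clinical dataset often want one shared
diagnostic model, but cannot pool their patient records. `ppsdt` implements a
collaborative training protocol that produces a **single information-gain
decision tree** over horizontally partitioned categorical data — the same
attribute schema at every hospital, each owning a disjoint set of records —
without any record or raw count ever leaving its hospital.

The key observation is that a decision-tree split decision needs only the
**frequency matrix** of each candidate attribute: the k×l table
`M_T[a, b] = #{records with T = t_a and class = c_b}` in the current
partition. Its column sums give the class distribution, its rows the
per-value class distributions, so

```
Entropy(D)   = Σ_i −(freq(c_i, D)/|D|) · log₂(freq(c_i, D)/|D|)
Entropy_T(D) = Σ_j (|t_j|/|D|) · Entropy(t_j)
IG(T)        = Entropy(D) − Entropy_T(D)
```

are all computable from the matrix alone. The protocol therefore exchanges
only encrypted matrices:

1. A **Trusted Authority** distributes one Paillier key pair to all hospitals
   and gives the untrusted **cloud** only the Paillier public key plus its own
   RSA pair.
2. Each round, every hospital counts its local matrices for the current
   partition, adds a secret session nonce *z* to every cell (so other holders
   of the shared Paillier key cannot read intercepted matrices),
   Paillier-encrypts cell by cell, and sends the matrices plus the RSA-sealed
   nonce to the cloud.
3. The cloud opens each nonce, removes the blinding **homomorphically**
   (multiplying each ciphertext by `g^(−z)`), sums corresponding cells across
   hospitals — the additive homomorphism
   `E(m₁)·E(m₂) mod n² = E(m₁+m₂)` — and broadcasts the pooled encrypted
   matrices.
4. Every hospital decrypts the pooled counts, computes information gain, and
   deterministically reaches the same split (ties by schema order); the cloud
   learns only the chosen attribute and recursion continues depth-first over
   the open partitions.

All hospitals end with the identical tree, which is provably the same tree a
single site would train on the pooled records — the package ships the
plaintext reference builder and checks node-for-node equality in its test
suite. What the design knowingly reveals to participants: pooled aggregate
frequencies and the pooled dataset size.

## Worked example

Simulate three hospitals with 20 records each (five binary symptom attributes
— Nausea `N`, Lumbar pain `LP`, Urine pushing `UP`, Micturition pains `MP`,
Burning of urethra `BU` — and four diagnosis classes 0–3), then train and
classify:

```
$ ppsdt simulate-data --hospitals 3 --n 20 --seed 7 --out run --paillier-bits 512 --rsa-bits 512
wrote 3 hospital datasets and run/session.json
$ ppsdt train --config run/session.json --out run/tree.json
trained in 8 rounds; wrote run/tree.json
$ ppsdt classify --tree run/tree.json --input "N=0,LP=0,UP=1,MP=1,BU=1"
2
```

The printed `2` is the diagnosis class (bladder inflammation) reached by the
single leaf this symptom vector selects. `run/tree.json` holds the shared
tree; 8 rounds means eight partitions needed a full encrypt–aggregate–decrypt
exchange. The library surface mirrors this pipeline (`ppsdt.dataset`,
`ppsdt.paillier`, `ppsdt.envelope`, `ppsdt.protocol`, `ppsdt.c45`).

On the classic 22-record aggregate whose Nausea matrix has rows
`[8, 3, 5, 0]` and `[0, 2, 0, 4]`:

```python
>>> from ppsdt.dataset import nausea_fixture
>>> from ppsdt.c45 import entropy, attribute_entropy, information_gain
>>> m, class_totals = nausea_fixture()
>>> round(entropy(class_totals), 4), round(attribute_entropy(m), 4), round(information_gain(m), 4)
(1.9495, 1.3248, 0.6247)
```

i.e. the pooled class entropy is 1.9495 bits, splitting on Nausea leaves
1.3248 bits, an information gain of 0.6247 bits.

`ppsdt benchmark --key-bits 512,1024,2048` writes a CSV of mean
encrypt/decrypt/aggregate times per key size; only the qualitative trend
(larger keys cost more) is meaningful across machines.

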