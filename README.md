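# nucleostates

Quantitative analysis of nucleosome organisation from MNase-style data:
dyad calling, nucleosome grouping, functional-state classification,
condition-switch detection, and integration of one-base-resolution
pioneer-factor binding borders.

## Who this is for

Chromatin and regulatory-genomics analysts working with MNase-seq fragment
midpoints, MNase-ChIP-seq histone-mark tracks and ChIP-exo-style 1-bp binding
borders, who want to move beyond per-nucleosome calls to *array-level*
functional states (how many nucleosomes, how tightly spaced, how regular,
carrying which marks, in which genomic context) and to ask how those states
reorganise between two conditions (e.g. vehicle vs androgen treatment).

## The model

Nucleosome `i` in a called map contributes a positioning factor and a
histone-mark factor:

```
lambda_i = S_i / W_i + omega * (mu - d_i)
beta_i   = sum_k  w_k * a_i^k * b_i
```

where `S_i` is the peak area of the smoothed midpoint density over the
footprint, `W_i` the footprint width, `d_i` the spacing to the next
nucleosome, `mu` the local average spacing (10-kb window), `omega` a spacing
weight, `a_i^k` the library-normalised mark-`k` signal on the footprint,
`b_i` the normalised occupancy signal and `w_k` per-mark weights.  Scanning
left to right, nucleosome `i+1` joins the running group while the similarity
ratio

```
gamma = (lambda_i beta_i - lambda_{i+1} beta_{i+1}) / sum_{n<=i} lambda_n beta_n
```

stays below 10% in absolute value (and the spacing stays within the 150-350
bp nucleosomal range).  Groups are summarised into feature vectors — member
count, mean spacing, Welch-PSD regularity, degree of positioning,
promoter/proximal/distal composition and eight mark signals — z-scored, and
K-means-clustered into nine functional states S1-S9 (S2 "accessible edge":
1-4 nucleosomes at ~180 bp; S4 "crowding array": 5-20 nucleosomes at ~211 bp
with repressive H3K9me3/H3K27me3; S5 the most regular; S8 "fuzzy"; ...).
Matched groups across two conditions yield a state-transition table and flags
for switches into relatively accessible states (RAS1: S4 to {S2,S3,S7,NFR};
RAS2: S3 to {S2,S6,NFR}).  Border pairs are reduced to their midpoint,
assigned to the nearest dyad within 100 bp, and scored for edge binding
(|dyad offset| in 50-60 bp).

A synthetic-data module generates every input with known ground truth —
phased arrays from nine state archetypes, a genome-wide spacing mixture
peaking at 187 bp, matched condition pairs drawn from a row-stochastic
transition matrix, and border pairs with a 13-14 bp modal gap — so every
stage is testable without external downloads.

## Worked example

```python
import nucleostates as ns

cfg = ns.SyntheticConfig()

# simulate a matched Veh/DHT pair and recover the transition structure
pair = ns.generate_condition_pair(cfg, states={"S4": 5000, "S3": 5000},
                                  seed=2, emit_reads=False, emit_marks=False)
matched = ns.match_regions(ns.truth_groups(pair.veh),
                           ns.truth_groups(pair.dht),
                           nucleosomes_b=pair.dht.nucleosomes)
tt = ns.transition_table(matched)
print(round(tt.switched["S4"], 1))               # 72.3
print(round(tt.row_percent.loc["S4", "S3"], 1))  # 45.2
print(round(tt.row_percent.loc["S3", "S2"], 1))  # 43.7
```

72.3% of the 5,000 simulated S4 ("crowding array") regions changed state
after treatment, 45.2% of them into S3, and 43.7% of S3 regions relaxed into
S2 — all within binomial sampling error of the generator's transition matrix
(0.721, 0.454 and 0.423), showing that region matching and transition
counting recover the encoded dynamics.  Calling dyads from raw midpoints and
classifying states works the same way:

```python
m = ns.generate_nucleosome_map(cfg, "Veh", n_regions=200, seed=1)
nucs = ns.call_dyads(m.midpoints, bandwidth=30)
print(ns.spacing_stats(nucs).mode)               # 187
```

The command-line interface mirrors the library
(`nucleostates simulate | call-nucleosomes | classify-states |
compare-states | borders | run | report`).

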