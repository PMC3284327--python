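# mpphap

Exact two-locus haplotype probabilities for advanced intercross
populations — two-way advanced intercross lines (AIL), eight-way
heterogeneous stock (HS), and the diversity outcross (DO) — on autosomes
and the X chromosome, with the founder-allele transition matrices and map
expansions needed to build hidden Markov models for genotype
reconstruction.

## The problem

Multiparent mouse populations accumulate recombination over many
generations of random mating, which sharpens QTL mapping but complicates
genotype reconstruction: an HMM over founder ancestry needs, for each
marker interval, the probability that a chromosome switches founders
between adjacent loci.  With a large number of mating pairs the two
haplotypes of an individual are independent, so two-locus *haplotype*
probabilities suffice.  Writing `p_s` for the frequency of the intact
`AA` haplotype (founder A at both loci) at generation `s` and `r` for the
meiotic recombination fraction between the loci, the populations follow
linear recurrences such as

```
AIL autosome:   p_{s+1} = (1-r) p_s + r/4,            p_s -> 1/4
DO/HS autosome: p_{s+1} = (1-r) p_s + r/64,           p_s -> 1/64
DO/HS X:        m_{s+1} = (1-r) f_s + r/64
                f_{s+1} = m_s/2 + (1-r) f_s/2 + r/128
```

with design-specific initial conditions (for HS/DO these come from an
exact Markov-chain treatment of the Collaborative Cross funnel and
sib-mating generations; for the unbalanced AIL X the recombinant terms
carry the sex- and generation-dependent allele frequencies
`q_s = 2/3 + (1/3)(-1/2)^s`).  The *map expansion* `dR/dr` at `r = 0`
(the breakpoint density on a random chromosome, per meiosis) is `s/2` for
the AIL autosome, `(7s+17)/8` for HS, and exactly 2/3 of the autosomal
value on the X.

Everything is cross-checked three ways: scalar recurrences with
re-derived closed forms, an independent full-table propagator, and a
seeded forward Monte-Carlo simulator of the actual breeding designs.

## Worked example

```python
>>> import mpphap as mp
>>> hs = mp.hs_alpha()                      # HS = DO with all progenitors at k = 1
>>> mp.precc_autosome_q(2, 0.01)            # AA freq of a transmitted pre-CC gamete
0.12128737499999998
>>> mp.do_recombinant(10, 0.01, hs)         # HS recombinant haplotypes at s = 10
0.10280478421932637
>>> mp.map_expansion_closed("hs", "A", 1)   # breakpoint density at s = 1
3.0
>>> tm = mp.transition_matrix("hs", "A", 10, 0.01)
>>> float(tm.entries[0, 0]), float(tm.entries[0, 1])   # HMM transition probabilities
(0.8971952157806736, 0.014686397745618054)
```

At `s = 10`, `r = 0.01`, 10.3% of HS haplotypes are recombinant, so an
HMM chain stays on the same founder with probability 0.897 across such an
interval.  The same numbers are available from the shell:

```
mpphap haplofreq --design hs --chrom A --s 10 --r 0.01
mpphap mapexp --design hs --chrom A --s-grid 1:10 --legacy-hs
mpphap transitions --design do --chrom A --s 5 --map map.csv --alpha alpha.json
mpphap simulate --design ail2 --chrom X --s 5 --r 0.1 --seed 1
```

where `map.csv` has columns `marker,chromosome,position_cM` (converted to
interval `r` via the Haldane or Kosambi map function) and `alpha.json`
gives the DO progenitor-generation weights `{"4": 0.2, ...}`.

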