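# vhhkit

Sequence intelligence for engineering camelid single-domain antibodies
(VHHs, "nanobodies").

VHHs bind antigen with a single variable domain. Lacking a light chain,
they rely on structural features of their own framework: the **Hallmark
residues** at IMGT positions 42/49/50/52 in FR2, which reshape the former
light-chain interface and often stabilize CDR3; **non-canonical
disulfides**, most often between a cysteine at position 55 and a
somatically introduced CDR3 cysteine, which lock CDR3 into its bioactive
conformation; and **Vernier zone** residues supporting the CDR loops.
Humanizing a VHH for therapeutic use means replacing framework residues
with those of the closest human germline without destroying these
features. `vhhkit` implements the sequence-level toolbox for that
problem, for antibody engineers and repertoire analysts:

* **Annotation** — IMGT numbering of raw sequences by germline profile
  transfer (ANARCI-style numbering tables are also read directly), region
  extraction under the IMGT, Kabat, Chothia and *combined* CDR
  definitions, Hallmark motifs, CDR3 lengths, non-canonical cysteine
  detection. The combined definition matters: position 40 is CDR1 under
  Kabat (FR2 under IMGT) and Cys55 is CDR2 under Kabat, so
  framework-based humanization under the combined definition leaves both
  alone.
* **Repertoire statistics** — per-position Shannon entropy
  `H(X) = −Σ p log₂ p` normalized by log₂ 21 (20 residues + gap),
  pairwise normalized mutual information
  `NMI(X,Y) = 2·MI(X,Y)/(H(X)+H(Y))`, and Ward-linkage clustering of
  positions on the distance `d = 1 − NMI` with a fixed cut height
  (default 1.1). On repertoires with motif-coupled position 40, the
  clustering recovers an *extended Hallmark* cluster {40, 42, 49, 50, 52}.
  Subset statistics (Hallmark-motif and Cys subsets), sequence-logo
  frequency matrices and CDR3 length distributions round this out.
* **Humanization** — closest-human-germline selection by framework
  identity, CDR grafting that retains Hallmark/Vernier/non-canonical-Cys
  residues (the *low-risk variant*), the anti-preADA substitution L12V,
  and risk-tiered stepwise or combinatorial variant enumeration
  (highest: 42/52 → bridged cysteines → 49/50 → Vernier → DE loop → rest),
  plus humanness scoring and a sequence-liability scan (deamidation,
  isomerization, N-glycosylation, unpaired Cys, CDR methionine).
* **SAR** — affinity-table ingestion (KD in nM, `nb` = non-binder), fold
  changes vs a reference (reductions above 2-fold count as relevant),
  matched molecular pairs (variant pairs differing by exactly one
  mutation), and per-mutation geometric-mean effect aggregation with
  knockout tallies.
* **Simulation** — a generator of synthetic VHH repertoires (Hallmark
  motif mixture, motif-conditional CDR3 lengths and cysteine pairs,
  Hallmark-coupled position 40) and of SAR tables with known
  multiplicative effects, so every analysis stage is testable without
  external data.

## Worked example

```python
import vhhkit as vk

db = vk.default_germline_db()                      # synthetic camelid + human scaffolds
parental = db.by_name("syncam-VHH-FERG*01").numbered

plan = vk.plan_humanization(parental, db, mode="stepwise")
print(plan.germline.name)                          # synhum-VH3-VGLW*01
print(round(vk.humanness(parental, db), 1))        # 87.5
print(round(vk.humanness(plan.low_risk_variant, db), 1))  # 91.2
for k in plan.key_mutations:
    print(k.notation, k.tier.label)
```

prints the risk-ordered candidate humanizations of the retained key
positions:

```
F42V highest
G52W highest
E49G high_solubility
R50L high_solubility
F78I significant_vernier
V87L significant_vernier
```

i.e. the low-risk graft already reaches 91.2% framework humanness, and
the remaining gap to the human germline sits entirely in Hallmark and
Vernier positions, each tagged with the risk its humanization carries.
On the bundled affinity series for two NKp30-binding VHHs, the same
mutations can be read out experimentally:

```python
from vhhkit.sar import load_example_affinity_table
table = {r.variant_id: r for r in load_example_affinity_table()}
vk.fold_change(table["VHH2-v1.3"], table["VHH2-v1.2"]).rounded   # 4.8  (V87L)
```

a 4.8-fold KD loss for humanizing Vernier residue 87 in that context —
above the 2-fold relevance threshold.

The same pipeline runs from the shell: `vhhkit simulate | annotate |
stats | humanize | sar` (see `vhhkit --help`); each subcommand writes a
plain-text bundle with a manifest for bit-identical re-runs.

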