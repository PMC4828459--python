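# abescount

Spectral-counting selection of S-acylated proteins from paired
+hydroxylamine / −hydroxylamine acyl-biotin-exchange (ABE) enrichment runs.

## The problem

S-acylation (commonly palmitoylation) attaches a fatty acid to a cysteine
through a thioester bond and is a major regulator of membrane association
in plants. The ABE chemistry purifies formerly S-acylated proteins:
hydroxylamine cleaves the thioester so the exposed cysteine can be
biotinylated and affinity-captured (+Hyd sample), while an untreated
control (−Hyd) captures only the nonspecific background of the resin.
Mass-spectrometry identification of both samples across biological
replicates (BRs) then turns the discovery problem into a counting one:
which proteins are credibly enriched in +Hyd over −Hyd?

`abescount` implements that computational half for proteomics analysts:
it consumes flat tables of peptide-spectrum matches (PSMs) with their
PeptideProphet/ProteinProphet-style posterior probabilities and produces
a tiered list of S-acylated candidates with a full rule trace, plus the
descriptive cross-tabulations used to characterise the resulting protein
set. A seeded synthetic-experiment generator with planted protein classes
lets the whole procedure be validated end-to-end.

## The method

Within each run, PSMs are kept when protein and peptide probabilities are
≥ 0.95; peptides matching two or more proteins anywhere in the dataset are
discarded, and a protein with no unique peptides is dropped. Spectra with
probability > 0.5 on unique peptides are indexed as spectral counts, and
each count is normalized to the run total (NSC = SpC / ΣSpC). For protein
*i* in replicate *r* the enrichment statistic is the NSC ratio

    R_ir = NSC_ir(+Hyd) / NSC_ir(−Hyd),

defined only when the protein is identified in both members of the pair.
A replicate *qualifies* the protein when it is identified only in +Hyd, or
when R_ir > 4 (a −Hyd count of zero exceeds any threshold). With *q* the
number of qualifying replicates and *t* the number of distinct unique
peptides seen in +Hyd runs, an ordered decision table assigns the tier:
exclusion-listed proteins (ribosomal, non-acyl thioester) are EXCLUDED;
q = 0 is NOT_CANDIDATE; q = 1 with t = 1 is removed as a singleton;
q ≥ 2 with t ≥ 2 is HIGH confidence (subtyped +Hyd-only vs ratio);
the remaining patterns are MEDIUM.

## Worked example

```sh
abescount simulate --seed 17 --out scratch/sim
abescount classify scratch/sim/BR*.tsv \
    --exclusions scratch/sim/exclusions.tsv --out scratch/out
abescount recover --classification scratch/out/classification.tsv \
    --truth scratch/sim/truth.tsv --out scratch/recovery.json
```

The same flow is scripted in `analysis/01_simulate.py` through
`analysis/04_annotation_tables.py`. With the default design (250 proteins:
50 each of exclusive acylated, leaky acylated, nonspecific, ribosomal
contaminant, and low-evidence singletons; 3 replicate pairs) at seed 17,
classification prints:

```
82 proteins reach the HIGH tier (50 +Hyd-only, 32 by ratio); 17 are
MEDIUM, 50 removed as single-replicate single-peptide identifications,
50 excluded as listed contaminants and 51 never qualify in any replicate.
```

All 50 exclusive acylated proteins land in HIGH via the +Hyd-only route;
the leaky (8-fold enriched) class splits between HIGH and MEDIUM according
to how many replicates clear the ratio threshold; every planted
contaminant is excluded. Over 20 seeds (`analysis/03_recovery.py`):

```
sensitivity: mean 0.972, min 0.930 over 20 seeds
false-discovery proportion: mean 0.011, max 0.040
every listed ribosomal contaminant was excluded in every run
```

`analysis/04_annotation_tables.py` tabulates the packaged reference
tables: the 52 S-acylated protein kinases split over iTAK classes
{1: 37, 2: 5, 4: 8, 5: 2} with 19 receptor-like cytoplasmic kinases, and
24 of the 80 DRM-enriched proteins (30.0%) fall in the high-confidence
set.

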