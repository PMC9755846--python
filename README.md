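# cdrlight

Tumor suppressor genes such as *CDKN2A* (9p21) are recurrently inactivated by
interstitial somatic copy-number deletion (SCND). Deletion breakpoints differ
between tumors, but the deleted fragments of a gene share a stable
intersection — the **common deletion region (CDR)**. For *CDKN2A* the
base-resolution CDR spans 5.1 kb (chr9:21,970,277–21,975,386, hg19), from the
*P16INK4A* promoter to intron-2, and a single qPCR amplicon placed inside it
can detect most *CDKN2A* deletions with a routine duplex assay.

`cdrlight` implements that analysis chain as a reusable library and CLI, for
molecular-pathology and cancer-genomics groups who want to design and
validate CDR-targeted copy-number assays:

* **intervals** — sweep-line coverage over cohorts of deletion fragments,
  CDR discovery (maximal-depth run with support-fraction and length rules),
  and amplicon containment scoring;
* **qpcr** — comparative-Ct quantification
  (`RCN = E^-(ΔCt_sample − ΔCt_calibrator)`, `E = 2`), a reference-gene
  informativeness gate (GAPDH mean Ct ≤ 34), paired tumor-vs-normal
  deletion/amplification calls by Student's t-test on replicate RCNs,
  titration efficiency, spike-in mixture linearity, and detection-limit
  estimation;
* **assoc** — OR/AND call merging, cross-product odds ratios with Wald CIs,
  chi-square, two-sided Fisher exact, and the Cochran–Armitage trend test;
* **synth** — seeded generators for planted-CDR cohorts, duplex qPCR plates
  with a cycle-scale Gaussian noise model, and clinical call tables with
  planted log-odds, plus a deterministic 139-sample preset reproducing a
  published gastric-carcinoma cross-tabulation margin-for-margin.

## Worked example

Simulate a 100-fragment deletion cohort whose planted CDR is contained in
90% of fragments, then recover it:

```console
$ cdrlight --seed 11 simulate cohort --out sim
$ cdrlight find-cdr --bed sim/cohort.bed --locus chr9:21800000-22200000
{
  "tool": "cdrlight 0.1.0",
  "region": "chr9:21970277-21975386",
  "region_length_kb": 5.1,
  "support_count": 91,
  "n_total": 100,
  "support_fraction": 0.91,
  "is_cdr": true,
  "alternates": []
}
```

The recovered region is base-identical to the planted 5.1 kb CDR; 91 of 100
fragments fully contain it (the planted containment probability was 0.9),
and it passes the default CDR rule (support ≥ 0.8 and length ≥ 1 kb).

Test the association between a deletion call and distant metastasis on the
margin-matching 139-sample preset:

```console
$ python -c "from cdrlight.synth import table2_preset; table2_preset().to_csv('calls.csv', index=False)"
$ cdrlight associate --calls calls.csv --outcome distant_metastasis \
      --positive-level positive --trend stage
{
  "table": {"a": 20, "b": 12, "c": 31, "d": 76},
  "odds_ratio": 4.09,
  "ci95": [1.78, 9.36],
  "chi_square": 11.921,
  "chi_square_p": 0.0006,
  "fisher_p": 0.0008,
  "trend": {"covariate": "stage", "z": 2.336, "p": 0.0195}
}
```

Of 32 metastasis-positive tumors, 20 were deletion-positive, against 31 of
107 metastasis-negative tumors: odds ratio (20·76)/(12·31) = 4.09,
chi-square p ≈ 0.0006. The trend test over pTNM stages I–II/III/IV gives
z = 2.34 (p ≈ 0.02) for an increasing deletion rate with stage.

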