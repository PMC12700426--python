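# sostempo

Temporal hierarchy of the bacterial SOS regulon: analysis pipeline and
matched synthetic-data generator.

## The scientific problem

When bacteria suffer DNA damage, a RecA nucleoprotein filament triggers
auto-cleavage of the LexA repressor and the SOS regulon is de-repressed.
In *Caulobacter crescentus* the SOS genes do not switch on simultaneously:
some promoters are induced early (detectable 20 min after mitomycin-C
exposure), others only later (40 min). `sostempo` implements the
computational workflow used to characterise this hierarchy and to ask what
drives it:

1. **Regulon calling.** A gene belongs to the SOS regulon when it is
   (i) induced in wild type under damage (log2FC > 1, *p* < 0.01,
   FDR < 0.1, all strict), (ii) de-repressed in a Δ*lexA*Δ*sidA* strain
   without damage, (iii) RecA-dependent (not induced in Δ*recA* under
   damage), and (iv) LexA-bound at its promoter (ChIP coverage).
   Differential expression uses median-of-ratios normalisation, a common
   negative-binomial dispersion (Var = μ + φμ²), a conditional NB exact
   test on group sums, and Benjamini–Hochberg FDR.
2. **Temporal classes.** Member genes are collapsed to transcription units
   (TUs); a TU promoter is *early* if induced by 20 min, *late* if only at
   40 min.
3. **LexA-box analysis.** Promoter windows (200 bp upstream, 75 bp
   downstream of the CDS start) are scanned for the dyad operator
   GTTC-N₇-GTTC with a seeded one-occurrence-per-sequence EM; boxes are
   scored against the learned PWM (log₂-odds), and features (distance to
   CDS, spacer length/GC, one-hot PCA) are compared between early and late
   promoters.
4. **ChIP coverage.** Tracks are rpm-normalised, Gaussian-smoothed
   (circular), reduced to promoter peak heights, summits and ±100 bp
   summit-to-gene assignments, bound fractions and CDS-anchored
   meta-profiles.
5. **Single-cell kinetics.** Area-normalised reporter traces are averaged,
   fitted with a four-parameter logistic F(t) = b + A/(1 + e^(−r(t−t₀)))
   (R² > 0.95 gate), and summarised by the induction time T_ind — the time
   at which the fitted mean reaches twice its initial value — plus the
   coefficient of variation across cells.
6. **Promoter strength.** The intrinsic promoter strength β_max is proxied
   by the log2FC of the repressor deletion versus wild type without damage;
   the pipeline reports its correlation (Pearson r²) with damage induction
   and its difference between early and late promoters, alongside basal
   RPKM, TU length and replication-origin distance.

Because the regulon, motif placement, peak positions, temporal classes and
per-cell promoter strengths are all *planted* by the built-in generator,
every stage can be validated end to end against ground truth without any
external download.

## Worked example

```sh
sostempo run --outdir demo --seed 7 --no-report
```

prints (and writes to `demo/summary.json`):

```json
{
  "consensus": "GTTCACCGAGCGTTC",
  "cv_strong": 0.29707823094250113,
  "cv_weak": 0.24250948090024937,
  "n_derepressed_dlexa": 40,
  "n_early_tus": 16,
  "n_genes": 200,
  "n_induced_wt20": 18,
  "n_induced_wt40": 40,
  "n_late_tus": 14,
  "n_member_tus": 30,
  "n_regulon_members": 40,
  "n_summits": 40,
  "p_beta_early_vs_late": 3.567368795444174e-06,
  "pct_early_bound": 100.0,
  "pct_late_bound": 100.0,
  "pearson_r": 0.9823677260753687,
  "r2_beta_vs_damage": 0.9650463492344906,
  "t_ind_strong_min": 36.25208544732658,
  "t_ind_weak_min": 47.995617535452524
}
```

Reading this: of 200 simulated genes, 18 are induced at 20 min and 40 at
40 min; all 40 planted SOS genes pass the three-criteria-plus-binding
filter, collapsing to 30 TUs (16 early, 14 late). The discovered operator
consensus carries both GTTC half-sites around a 7-bp spacer. The β_max
proxy explains 96.5% of the variance in damage induction (r² ≈ 0.97) and
separates early from late promoters (Mann–Whitney p ≈ 4·10⁻⁶). In the
single-cell module the promoter with twice the strength doubles its initial
fluorescence at ≈36 min versus ≈48 min for the weaker one, with
cell-to-cell CVs of ≈0.25–0.30. The output directory also contains the
simulated inputs (FASTA/GFF3/TSV/bedGraph), per-stage tables, the ground
truth, and a manifest with checksums; `--report` adds figures (volcano,
PCA, strength scatter, meta-profile, traces).

Every stage is also available on its own (`sostempo simulate | diffexpr |
regulon | lexabox | chip | kinetics | strength`) and as plain library
functions (`sostempo.diffexpr.run_contrast`, `sostempo.kinetics.fit_logistic`,
…).

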