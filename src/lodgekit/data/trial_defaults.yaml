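# Default field-trial generator configuration.
#
# Group means and standard errors are transcribed from the summary tables of
# a published two-variety (YJRZ inbred, YZ889 hybrid) rice field trial
# comparing farmers' fertilizer practice (FFP) with optimized nitrogen
# management (OPT) in a split-plot design with four replicate plots.  They
# are configuration, not hard-coded truth: edit freely to emulate other
# trials.  Plot-level sd is derived as se*sqrt(n_replicates); culm-level sd
# defaults to sd_culm_factor times the plot sd.
#
# Units: length_cm (cm), diameter_mm/wall_mm (mm), dry_mg (mg), break_N (N),
# e_gpa (GPa), bm_gfcm (gf*cm), plant_height_cm (cm).
n_replicates: 4
culms_per_plot: 10
span_cm: 5.0
elastic_load_N: 1.0
sd_culm_factor: 2.0
groups:
  YJRZ:
    FFP:
      plant_height_cm: {mean: 104.0, se: 0.9}
      internodes:
        1:
          length_cm: {mean: 3.4, se: 0.1}
          diameter_mm: {mean: 5.89, se: 0.14}
          wall_mm: {mean: 0.93, se: 0.04}
          dry_mg: {mean: 65.6, se: 2.9}
        2:
          length_cm: {mean: 8.1, se: 0.2}
          diameter_mm: {mean: 5.45, se: 0.14}
          wall_mm: {mean: 0.67, se: 0.03}
          dry_mg: {mean: 93.2, se: 3.6}
          break_N: {mean: 9.1, se: 0.8}
          e_gpa: {mean: 0.57, se: 0.09}
          bm_gfcm: {mean: 1155.3, se: 102.7}
        3:
          length_cm: {mean: 16.9, se: 0.4}
          diameter_mm: {mean: 4.85, se: 0.14}
          wall_mm: {mean: 0.54, se: 0.02}
          dry_mg: {mean: 126.1, se: 6.7}
          break_N: {mean: 6.0, se: 0.6}
          e_gpa: {mean: 1.9, se: 0.14}
          bm_gfcm: {mean: 760.0, se: 76.2}
    OPT:
      plant_height_cm: {mean: 110.1, se: 3.3}
      internodes:
        1:
          length_cm: {mean: 2.8, se: 0.2}
          diameter_mm: {mean: 6.18, se: 0.18}
          wall_mm: {mean: 1.04, se: 0.02}
          dry_mg: {mean: 69.4, se: 4.5}
        2:
          length_cm: {mean: 6.8, se: 0.5}
          diameter_mm: {mean: 6.10, se: 0.19}
          wall_mm: {mean: 0.80, se: 0.02}
          dry_mg: {mean: 110.5, se: 7.6}
          break_N: {mean: 11.7, se: 0.8}
          e_gpa: {mean: 0.33, se: 0.04}
          bm_gfcm: {mean: 1490.3, se: 101.5}
        3:
          length_cm: {mean: 13.2, se: 0.6}
          diameter_mm: {mean: 5.49, se: 0.15}
          wall_mm: {mean: 0.67, se: 0.03}
          dry_mg: {mean: 145.6, se: 5.9}
          break_N: {mean: 9.3, se: 0.3}
          e_gpa: {mean: 1.26, se: 0.05}
          bm_gfcm: {mean: 1186.5, se: 32.0}
  YZ889:
    FFP:
      plant_height_cm: {mean: 102.9, se: 1.9}
      internodes:
        1:
          length_cm: {mean: 3.6, se: 0.3}
          diameter_mm: {mean: 5.55, se: 0.10}
          wall_mm: {mean: 0.92, se: 0.01}
          dry_mg: {mean: 55.9, se: 4.6}
        2:
          length_cm: {mean: 8.7, se: 0.3}
          diameter_mm: {mean: 5.21, se: 0.12}
          wall_mm: {mean: 0.65, se: 0.02}
          dry_mg: {mean: 103.8, se: 7.6}
          break_N: {mean: 7.9, se: 0.6}
          e_gpa: {mean: 0.64, se: 0.04}
          bm_gfcm: {mean: 1005.0, se: 70.6}
        3:
          length_cm: {mean: 17.8, se: 0.4}
          diameter_mm: {mean: 4.68, se: 0.16}
          wall_mm: {mean: 0.50, se: 0.01}
          dry_mg: {mean: 126.3, se: 9.4}
          break_N: {mean: 5.7, se: 0.5}
          e_gpa: {mean: 2.31, se: 0.32}
          bm_gfcm: {mean: 728.8, se: 58.0}
    OPT:
      plant_height_cm: {mean: 108.8, se: 2.1}
      internodes:
        1:
          length_cm: {mean: 3.4, se: 0.2}
          diameter_mm: {mean: 5.93, se: 0.06}
          wall_mm: {mean: 1.03, se: 0.02}
          dry_mg: {mean: 70.3, se: 6.5}
        2:
          length_cm: {mean: 7.1, se: 0.5}
          diameter_mm: {mean: 5.84, se: 0.08}
          wall_mm: {mean: 0.79, se: 0.02}
          dry_mg: {mean: 114.4, se: 10.2}
          break_N: {mean: 12.1, se: 0.4}
          e_gpa: {mean: 0.56, se: 0.11}
          bm_gfcm: {mean: 1548.4, se: 54.2}
        3:
          length_cm: {mean: 14.2, se: 0.5}
          diameter_mm: {mean: 5.56, se: 0.07}
          wall_mm: {mean: 0.61, se: 0.01}
          dry_mg: {mean: 164.1, se: 8.0}
          break_N: {mean: 9.3, se: 0.3}
          e_gpa: {mean: 1.48, se: 0.16}
          bm_gfcm: {mean: 1184.3, se: 36.6}
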