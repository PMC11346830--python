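# 14th 5-Year Plan (2021-2025) development goals for Jilin Province
# and the projected 2025 permanent population used to compute rates.
population_2025: 22343500
targets:
  beds_per_thousand: 7.50
  physicians_total: 85100
  physicians_per_thousand: 3.54
  nurses_total: 110000
  nurses_per_thousand: 4.20
  doctor_nurse_ratio: 1.20
  pharmacists_total: 13000
  pharmacists_per_thousand: 0.54
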