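# Synthetic parameter set for the AI-2 production component.
#
# The original experimentally derived rate constants and initial
# concentrations of this pathway are not printed in any source packaged
# here; this file is a synthetic stand-in, calibrated once so that the
# continuous (RK4) trace of the model reproduces the published qualitative
# behaviour of all 21 species over a horizon of 10,000 time units:
#   - both genes constant and positive,
#   - Nutrients and Putrescine decaying to zero (finite resources),
#   - AI2_Out, the mRNAs/proteins and Decarb_SAM rising to a plateau,
#   - the pathway intermediates peaking once and returning to zero,
#   - AI2_In_Phase2, Met, SAM and Spermidine falling, rising to a peak,
#     and falling back to zero.
rate_constants:
  bio_reac: 0.09
  AdoMet: 0.9
  MethyTrans: 0.3
  SAM_Decarb: 0.15
  SAH_Hydro: 0.03
  SRH_cleave: 0.12
  Met_recover: 0.18
  AI2_syn: 0.012
  DPD_deg: 0.33
  AI2_excret: 0.15
  SpeE_syn: 6.0e-05
  MTR_syn: 0.03
  MTR_excret: 0.15
  Spermi_util: 0.06
  Polyamin_util: 0.03
  LuxS_transcription: 1.2
  LuxS_translation: 0.6
  LuxS_mRNA_deg: 0.12
  LuxS_prot_deg: 0.12
  pfs_transcription: 1.2
  pfs_translation: 0.6
  Pfs_mRNA_deg: 0.12
  Pfs_prot_deg: 0.12
initial_marking:
  Adenine: 0
  AI2_In_Phase2: 30
  AI2_Out: 0
  Decarb_SAM: 0
  DPD: 0
  Homocys: 0
  luxS_gene: 1
  LuxS_mRNA: 4
  LuxS_prot: 10
  Met: 400
  MTA: 0
  MTR: 0
  Nutrients: 3000
  pfs_gene: 1
  Pfs_mRNA: 4
  Pfs_prot: 10
  Putrescine: 2000
  SAH: 0
  SAM: 1200
  Spermidine: 300
  SRH: 0
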