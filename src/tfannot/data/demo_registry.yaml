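# Demonstration registry: 8 signature domains and 8 TF/TC families.
#
# The domain profiles are built from the seed alignments under
# alignments/ (8 members each).  Cutoffs were calibrated on those member
# sequences (component-wise minima of their hmmsearch bit scores, with a
# 5-bit margin) in the spirit of family-calibrated thresholds.
version: demo-1

domains:
  - id: Homeobox
    type: DBD
    sequence_cutoff: 120.0
    domain_cutoff: 119.0
    source: family_calibrated
    profile: alignments/Homeobox.afa
  - id: START
    type: AD
    sequence_cutoff: 130.0
    domain_cutoff: 130.0
    source: family_calibrated
    profile: alignments/START.afa
  - id: zf-C2H2
    type: DBD
    sequence_cutoff: 65.0
    domain_cutoff: 65.0
    source: family_calibrated
    profile: alignments/zf-C2H2.afa
  - id: WRKY
    type: DBD
    sequence_cutoff: 118.0
    domain_cutoff: 117.0
    source: family_calibrated
    profile: alignments/WRKY.afa
  - id: Myb_DNA-binding
    type: DBD
    sequence_cutoff: 102.0
    domain_cutoff: 101.0
    source: family_calibrated
    profile: alignments/Myb_DNA-binding.afa
  - id: B3
    type: DBD
    sequence_cutoff: 159.0
    domain_cutoff: 159.0
    source: family_calibrated
    profile: alignments/B3.afa
  - id: Aux_IAA
    type: TC
    sequence_cutoff: 121.0
    domain_cutoff: 121.0
    source: family_calibrated
    profile: alignments/Aux_IAA.afa
  - id: RNase_T
    type: FD
    sequence_cutoff: 117.0
    domain_cutoff: 117.0
    source: family_calibrated
    profile: alignments/RNase_T.afa

families:
  # Homeobox superfamily: plain homeobox proteins vs HD-ZIP, which
  # additionally requires the START auxiliary domain.
  - name: HB-other
    category: TF
    required: [Homeobox]
    forbidden: [RNase_T]
    superfamily: Homeobox
  - name: HD-ZIP
    category: TF
    required: [Homeobox]
    auxiliary: [START]
    forbidden: [RNase_T]
    superfamily: Homeobox
  # B3 superfamily: ARF = B3 DBD plus the Aux/IAA auxiliary domain.
  - name: B3
    category: TF
    required: [B3]
    forbidden: [RNase_T]
    superfamily: B3
  - name: ARF
    category: TF
    required: [B3]
    auxiliary: [Aux_IAA]
    forbidden: [RNase_T]
    superfamily: B3
  - name: C2H2
    category: TF
    required: [zf-C2H2]
    forbidden: [RNase_T]
  - name: WRKY
    category: TF
    required: [WRKY]
    forbidden: [RNase_T]
  - name: MYB
    category: TF
    required: [Myb_DNA-binding]
    forbidden: [RNase_T]
  # Coregulator family: Aux/IAA proteins carry the Aux_IAA domain but no
  # DBD; evaluated only for proteins with no TF call.
  - name: AUX/IAA
    category: TC
    required: [Aux_IAA]
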