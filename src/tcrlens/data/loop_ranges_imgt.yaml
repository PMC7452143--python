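# Default CDR / HV4 loop residue ranges for TCR variable domains in
# IMGT numbering.  These are a documented starting point only: real
# structures are deposited in many author-specific numbering schemes, so
# loop ranges must be curated per entry and passed in the annotation
# config -- the library never guesses loop boundaries.
#
# To use, merge into a full annotation config (which must also define
# `roles`, `variable_domains` and `groove_helices`).
loops:
  CDR1a: [27, 38]
  CDR2a: [56, 65]
  HV4a: [81, 86]
  CDR3a: [105, 117]
  CDR1b: [27, 38]
  CDR2b: [56, 65]
  HV4b: [81, 86]
  CDR3b: [105, 117]
disulfide_cys:
  TCR_alpha: [23, 104]
  TCR_beta: [23, 104]
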