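# Example region scheme for the Mot1 heavy chain (chain M).
# The RecA1/RecA2 boundary inside the Swi2/Snf2 domain is not structurally
# annotated for this organism; the 1010 split below is a working choice that
# separates all known RecA1-side sites (<= 1008) from RecA2-side sites
# (>= 1013) and should be replaced by a user-supplied scheme for other
# proteins.
regions:
  M:
    - {name: NTD, start: 1, end: 97}
    - {name: latch, start: 98, end: 142}
    - {name: NTD2, start: 143, end: 778}
    - {name: linker, start: 779, end: 786}
    - {name: RecA1, start: 787, end: 1010}
    - {name: RecA2, start: 1011, end: 1890}
lobe_regions: [RecA1, RecA2]
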