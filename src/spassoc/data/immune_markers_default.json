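{
  "B cells": ["MS4A1", "CD79A", "CD79B", "CD19", "BANK1", "IGKC"],
  "T cells": ["CD3D", "CD3E", "CD3G", "CD2", "TRAC", "IL7R"],
  "Macrophages": ["CD68", "CD163", "LYZ", "AIF1", "MRC1", "ITGAM"],
  "Neutrophils": ["FCGR3B", "CSF3R", "S100A8", "S100A9", "CXCR2", "FPR1"],
  "NK": ["NKG7", "GNLY", "KLRD1", "NCR1", "KLRF1", "PRF1"]
}
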