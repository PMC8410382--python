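{
  "version": 1,
  "comment": "Gram equivalents of historical Chinese mass units by dynasty. 1 Jin = 16 Liang; 1 Liang = 10 Qian; 1 Qian = 10 Fen (nominal subdivision; the printed gram values are authoritative and are used verbatim).",
  "dynasties": {
    "Tang": {"Jin": 661.0, "Liang": 41.31, "Qian": 1.721, "Fen": 0.17},
    "Song": {"Jin": 663.0, "Liang": 40.0, "Qian": 4.0, "Fen": 0.4},
    "Yuan": {"Jin": 663.0, "Liang": 40.0, "Qian": 4.0, "Fen": 0.4},
    "Ming": {"Jin": 590.0, "Liang": 36.9, "Qian": 3.69, "Fen": 0.37},
    "Qing": {"Jin": 590.0, "Liang": 36.9, "Qian": 3.69, "Fen": 0.37}
  }
}
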