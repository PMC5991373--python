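[
  {
    "id": 1,
    "rule": "(Q1|Q2)&Q3&any(Q3A,Q3B,Q4,Q5)",
    "description": "Yes to Q1 or Q2, Q3, and any item from Q3A-Q5 (provider diagnosis plus round patches plus any supporting feature).",
    "source_confidence": "text_verified"
  },
  {
    "id": 2,
    "rule": null,
    "description": "Published only in the algorithm figure; supply a transcription before use.",
    "source_confidence": "figure_transcribed"
  },
  {
    "id": 3,
    "rule": "(Q1|Q2)&Q3&Q3A&any(Q3B,Q4,Q5)",
    "description": "Yes to Q1 or Q2, Q3, Q3A, and any item from Q3B-Q5 (strengthens algorithm 1 by requiring regrowth).",
    "source_confidence": "text_verified"
  },
  {
    "id": 4,
    "rule": null,
    "description": "Published only in the algorithm figure; supply a transcription before use.",
    "source_confidence": "figure_transcribed"
  },
  {
    "id": 5,
    "rule": "Q3&any(Q3A,Q3B,Q4,Q5)",
    "description": "Yes to Q3 and any item from Q3A-Q5 (round patches plus any supporting feature; no provider diagnosis required).",
    "source_confidence": "text_verified"
  },
  {
    "id": 6,
    "rule": null,
    "description": "Published only in the algorithm figure; supply a transcription before use.",
    "source_confidence": "figure_transcribed"
  },
  {
    "id": 7,
    "rule": null,
    "description": "Published only in the algorithm figure; supply a transcription before use.",
    "source_confidence": "figure_transcribed"
  },
  {
    "id": 8,
    "rule": null,
    "description": "Published only in the algorithm figure; supply a transcription before use.",
    "source_confidence": "figure_transcribed"
  },
  {
    "id": 9,
    "rule": null,
    "description": "Published only in the algorithm figure; supply a transcription before use.",
    "source_confidence": "figure_transcribed"
  }
]
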