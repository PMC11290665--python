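{
  "acclim_results.csv": "9bb9e541af57bd9175419db0c1202f1314a8a49370548b47052e4cb0e363dd86",
  "bleaching_scores.csv": "6d4e8c78fc967adf15a29f3e53fc8da2d3ce129672968fcd646833626da98da9",
  "genets.csv": "6b9bec87414dfed0414cd0bf281d111f26e178cdbfa5413a61a28b727f92ff03",
  "letters.csv": "a4f6c16c6d4ddc8d0ee40b894415f186f6f6c4a5c3824fb25bfe88aed943847f",
  "popstats.json": "bdcaa2fe0a1241794fb40f23edbec90218cd6306ccca496c124ca57e89549f0b",
  "responses.csv": "14f59bbce1698236fa229af02c133f9f08f3adab2cf0b823f11909780355951b"
}
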