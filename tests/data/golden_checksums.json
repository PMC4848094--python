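{
  "alignments_FP_WT_rep1.tsv": "99f7953ffbbc709e66208eddf86165a434a152ddf0a7daf5cd510ab84fa1d700",
  "alignments_FP_WT_rep2.tsv": "f1040460c9dcd5132c5ac24047aad0f196e6aad5d8ca7f2b70b718b31673b415",
  "alignments_FP_mut_rep1.tsv": "207f16e76826772b9701b68f66c670d88f59d1d383f1ee1b2e803ea357a9bcf1",
  "alignments_FP_mut_rep2.tsv": "612c7f893698477fa9b2402aa97764bf7ea6f5aa0935cc662a57a2b7e03fed47",
  "alignments_total_WT_rep1.tsv": "2e8b2ff5f25efc81839cf9c12a581c2795f22e192b3c03afc0e4dc51f28bb77d",
  "alignments_total_WT_rep2.tsv": "0e2203f8f66eebdbe7dd637d394d1e615afbdefcecec7c28f770aa49f3a13656",
  "alignments_total_mut_rep1.tsv": "944b35c3e65ecad4e670027fe15a5c4d5761b16ba513ab54c7ac09ff9afd7882",
  "alignments_total_mut_rep2.tsv": "05f5551faf92cc4075b495778b6eb0156cf4c3d113880654af0fabbe2b3b11bc",
  "annotation.tsv": "edd454df4b1a1d221e44279090985f516a7caa9eb1906d8f0a60e0d913d8e0f5",
  "correlations.tsv": "64c3ad72ccabb0bc134a039d87d575e5f33bab32029cb68655bc1136045a7df1",
  "counts.tsv": "aeafdd9f2fc763fa21c08859528bfa8f5c6161f0780879fef2b0164c71a88f71",
  "discards.tsv": "2208bf45d40fa6f127b3c9b0e313b9c2eb8908f8947f14d5dc45502633933b27",
  "groups.tsv": "1ba9905dc56b70e385f8aabf1c72f51f90a312772046edf5f5defe3a0f39af23",
  "groups_summary.tsv": "0d48ded88a7200c375a50c36985508e686f9098c703cfa02e67eb6e5ed321d4a",
  "groups_truth.tsv": "ca3e352a9f33a1ce1581121c009ae240bcba928cc6c87acbd4f5cff0011edcab",
  "peaks.tsv": "b4d335fb36ba61e14df2d6ff80d07f1a20841a5652110b3d8cc7e75c7b93c6a9",
  "profile.tsv": "dcc5cf09b532a04caaabc7277939f52ce5c636abba1658ee6ae9cca98965519e",
  "ratios.tsv": "9523e3f7a5e93e33cee7ecdfaeb26437544d37a2dcb866a1f9ad3f1cde4d515a",
  "te.tsv": "db885800a8dd9747c55f2959735400eac73e150bfabf2f4e145ddedfde30885c",
  "trace.csv": "06f3f6ebae029cc72ce21cb66f46cbb2554e554b08304ee50ee4d7d1f83d6d74",
  "truth.tsv": "d8109e70ae09b263915e1675e3437ba7fcdd360dbb1b94f4de27514ef9bc8f12"
}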