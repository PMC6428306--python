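{
  "$id": "exonmsbf-report-v1",
  "description": "Evaluation report written by `exonmsbf evaluate`.",
  "required": {
    "schema": "str",
    "n_records": "int",
    "n_exons": "int",
    "auc": "float",
    "roc": "dict",
    "ac_by_range": "dict",
    "ac_best_threshold": "dict",
    "n_exons_by_range": "dict",
    "n_thresholds": "int",
    "package_version": "str"
  },
  "roc_required": {
    "thresholds": "list",
    "sensitivity": "list",
    "specificity": "list"
  }
}
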