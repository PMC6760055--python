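{
  "batches.csv": "39ff0d564b94c96d01b51cbe2e43c70a00bb8ca13dd8137321889d29584c9247",
  "design.csv": "445a6f75b7d1f194f166628dbc76657fbf0e05bff814e7f6d7f75fbcabad0456",
  "factors.csv": "92b05f3c87b209985edc4190a6c28b5798c363ce3a1c07a0a55abea50c4049ca",
  "grading_batches.csv": "4f26734dc8538406fc30f43b83ac10e57728dacf032534efc3de94b92daf7113",
  "reference_models.json": "7aca094e8ad86b6286dc778a01853103aaced1c1c5ac10f51cb53f06a58c2952",
  "responses.csv": "75ae8388d4d5654bd0538f703b645ab79a5c05afd36cdc4441111a0aad6f59ec"
}
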