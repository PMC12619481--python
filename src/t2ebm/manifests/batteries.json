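{
  "CVLT": {
    "factors": {
      "immediate_recall": [
        "trial_1", "trial_2", "trial_3", "trial_4", "trial_5",
        "trial_1_5", "trial_b"
      ],
      "delayed_recall": [
        "short_delay_free_recall", "short_delay_cued_recall",
        "long_delay_free_recall", "long_delay_cued_recall"
      ],
      "intrusion_repetition": [
        "free_recall_intrusions", "cued_recall_intrusions",
        "total_intrusions", "total_repetitions"
      ],
      "delayed_recognition": [
        "long_delay_true_positive", "long_delay_false_positive"
      ]
    }
  },
  "STROOP": {
    "factors": {
      "correct_and_reaction_time": [
        "correct_number", "congruent_correct_number",
        "congruent_reaction_time", "incongruent_correct_number",
        "incongruent_reaction_time", "pronunciation_relevant_correct_number",
        "pronunciation_relevant_reaction_time", "irrelevant_correct_number",
        "irrelevant_reaction_time"
      ],
      "error_and_omission": ["error_number", "omission_number"]
    }
  },
  "WCST": {
    "factors": {
      "overall_and_flexibility": [
        "total_response", "total_errors", "pct_total_errors",
        "total_perseverative_responses", "pct_total_perseverative_responses",
        "total_nonperseverative_errors", "pct_total_nonperseverative_errors",
        "time"
      ],
      "perseverative_errors": [
        "perseverative_errors", "pct_perseverative_errors"
      ],
      "abstract_thinking": [
        "total_correct_responses", "conceptual_responses",
        "failure_to_maintain_set"
      ],
      "learning_ability": ["complete_first_category", "learning_to_learn"]
    }
  }
}
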