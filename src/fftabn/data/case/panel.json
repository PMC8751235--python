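[
  {
    "id": "E1",
    "professional_position": "Senior academic/research fellow",
    "service_years": ">=30",
    "education_level": "Ph.D.",
    "job_title": "Director/Captain or Chief Engineer"
  },
  {
    "id": "E2",
    "professional_position": "Engineer",
    "service_years": "20-29",
    "education_level": "Master's degree",
    "job_title": "Department Manager or Chief Officer"
  },
  {
    "id": "E3",
    "professional_position": "Junior academic/research fellow",
    "service_years": "10-19",
    "education_level": "Master's degree",
    "job_title": "Director/Captain or Chief Engineer"
  },
  {
    "id": "E4",
    "professional_position": "Senior academic/research fellow",
    "service_years": "20-29",
    "education_level": "Ph.D.",
    "job_title": "Senior Captain or Senior Chief Engineer"
  },
  {
    "id": "E5",
    "professional_position": "Engineer",
    "service_years": "10-19",
    "education_level": "Master's degree",
    "job_title": "Department Manager or Chief Officer"
  }
]
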