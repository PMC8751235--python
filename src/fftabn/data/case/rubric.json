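{
  "professional_position": {
    "Senior academic/research fellow": 5,
    "Junior academic/research fellow": 4,
    "Engineer": 3,
    "Technician": 2,
    "Worker": 1
  },
  "service_years": {
    ">=30": 5,
    "20-29": 4,
    "10-19": 3,
    "6-9": 2,
    "<=5": 1
  },
  "education_level": {
    "Ph.D.": 5,
    "Master's degree": 4,
    "B.S. or B.E.": 3,
    "Junior college": 2,
    "School level": 1
  },
  "job_title": {
    "Senior Captain or Senior Chief Engineer": 5,
    "Director/Captain or Chief Engineer": 4,
    "Department Manager or Chief Officer": 3,
    "Manufacturing Supervisor": 2,
    "Ratings": 1
  }
}
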