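# Default Master Surgical Schedule template: weekly assignment of surgical
# specialties to the three ORs, Monday-Friday, two 360-minute sessions per
# day (08-14 h and 14-20 h).
session_duration_min: 360
session_start: {morning: "08:00", afternoon: "14:00"}
rooms:
  OR1:
    monday: {morning: Maxillo-Facial Plastic, afternoon: Neurosurgery}
    tuesday: {morning: Otolaryngology, afternoon: Urology}
    wednesday: {morning: Neurosurgery, afternoon: Neurosurgery}
    thursday: {morning: Neurosurgery, afternoon: Urology}
    friday: {morning: Maxillo-Facial Plastic, afternoon: Maxillo-Facial Plastic}
  OR2:
    monday: {morning: General, afternoon: General}
    tuesday: {morning: Neonatal, afternoon: Neonatal}
    wednesday: {morning: Hepatobiliary, afternoon: Hepatobiliary}
    thursday: {morning: Urology, afternoon: Urology}
    friday: {morning: Orthopedy, afternoon: Urology}
  OR3:
    monday: {morning: Urology, afternoon: Urology}
    tuesday: {morning: Gastrointestinal, afternoon: Orthopedy}
    wednesday: {morning: Orthopedy, afternoon: Orthopedy}
    thursday: {morning: Neonatal, afternoon: General}
    friday: {morning: Urology, afternoon: Urology}
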