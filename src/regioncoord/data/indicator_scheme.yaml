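# Default 20-indicator evaluation scheme: three systems (economy, society,
# healthcare), eight subsystems (Z1-Z8), all indicators positive-direction.
# direction may be overridden per indicator ("negative" flips normalization).
indicators:
  - {id: x1,  name: "GDP",                                                          unit: "100 Million Yuan", direction: positive, subsystem: Z1, system: economy}
  - {id: x2,  name: "Fiscal Revenue",                                               unit: "100 Million Yuan", direction: positive, subsystem: Z1, system: economy}
  - {id: x3,  name: "Industrial Proportion in GDP",                                 unit: "%",                direction: positive, subsystem: Z2, system: economy}
  - {id: x4,  name: "Proportion of Tertiary Industry in GDP",                       unit: "%",                direction: positive, subsystem: Z2, system: economy}
  - {id: x5,  name: "Per-capita GDP",                                               unit: "Yuan",             direction: positive, subsystem: Z3, system: economy}
  - {id: x6,  name: "Per-capita Disposable Income of Urban Residents",              unit: "Yuan",             direction: positive, subsystem: Z3, system: economy}
  - {id: x7,  name: "Per-capita Disposable Income of Rural Residents",              unit: "Yuan",             direction: positive, subsystem: Z3, system: economy}
  - {id: x8,  name: "General Public Service Expenditure",                           unit: "100 Million Yuan", direction: positive, subsystem: Z4, system: society}
  - {id: x9,  name: "General Public Budget Expenditure",                            unit: "100 Million Yuan", direction: positive, subsystem: Z4, system: society}
  - {id: x10, name: "Urban and Rural Residents in Basic Endowment Insurance",       unit: "10,000 Persons",   direction: positive, subsystem: Z5, system: society}
  - {id: x11, name: "Persons in the Unemployment Insurance Program",                unit: "10,000 Persons",   direction: positive, subsystem: Z5, system: society}
  - {id: x12, name: "Urban Residents in Minimum Living Security Program",           unit: "Persons",          direction: positive, subsystem: Z6, system: society}
  - {id: x13, name: "Assistant Doctors per 1,000 Residents",                        unit: "Unit",             direction: positive, subsystem: Z7, system: healthcare}
  - {id: x14, name: "Registered Nurses per 1,000 Residents",                        unit: "Unit",             direction: positive, subsystem: Z7, system: healthcare}
  - {id: x15, name: "Number of Beds per 1,000 Residents",                           unit: "Unit",             direction: positive, subsystem: Z7, system: healthcare}
  - {id: x16, name: "Urban and Rural Households in the Basic Health Care Program",  unit: "10,000 persons",   direction: positive, subsystem: Z7, system: healthcare}
  - {id: x17, name: "Birth Rate",                                                   unit: "permille",         direction: positive, subsystem: Z7, system: healthcare}
  - {id: x18, name: "Number of Tertiary Hospitals",                                 unit: "Unit",             direction: positive, subsystem: Z8, system: healthcare}
  - {id: x19, name: "Number of Township Hospitals",                                 unit: "Unit",             direction: positive, subsystem: Z8, system: healthcare}
  - {id: x20, name: "Number of Village Clinics",                                    unit: "Unit",             direction: positive, subsystem: Z8, system: healthcare}
subsystem_names:
  Z1: Economic aggregate
  Z2: Economic structure
  Z3: Economic efficiency
  Z4: Public investment
  Z5: Social security
  Z6: Social assistance
  Z7: Healthcare service accessibility
  Z8: Healthcare service fairness
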